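"""CCIM construction, filtering, standardization and file round trips."""

import numpy as np
import pandas as pd
import pytest

from ccibae import (
    ExpressionMatrix,
    LigandReceptorDB,
    build_ccim,
    filter_active_features,
    load_expression,
    load_lr_database,
    read_ccim,
    standardize_features,
    write_ccim,
)
from ccibae.ccim import write_cell_types, write_expression
from ccibae.errors import (
    ConstantFeatureError,
    EmptyFeatureSpaceError,
    EmptyPairSetError,
    FormatError,
    ValidationError,
)
from conftest import make_ccim


class TestExpressionIO:
    def test_csv_load_preserves_names_and_values(self, tmp_path):
        f = tmp_path / "expr.csv"
        f.write_text("cell,G1,G2,G3,G4\nc1,1,0,2,0\nc2,0,3,0,1\nc3,5,0,0,0\n")
        expr = load_expression(f, format="csv")
        assert expr.n_cells == 3 and expr.n_genes == 4
        assert expr.cell_ids == ["c1", "c2", "c3"]
        assert expr.gene_ids == ["G1", "G2", "G3", "G4"]
        assert expr.values[2, 0] == 5

    @pytest.mark.parametrize("fmt", ["csv", "tsv", "mtx_triplet"])
    def test_write_load_round_trip(self, toy_expr, tmp_path, fmt):
        suffix = {"csv": "csv", "tsv": "tsv", "mtx_triplet": "mtx"}[fmt]
        f = tmp_path / f"expr.{suffix}"
        write_expression(toy_expr, f, format=fmt)
        types = tmp_path / "types.tsv"
        write_cell_types(toy_expr, types)
        back = load_expression(f, format=fmt, cell_types_path=types)
        np.testing.assert_allclose(back.values, toy_expr.values)
        assert back.cell_ids == toy_expr.cell_ids
        assert back.gene_ids == toy_expr.gene_ids
        assert back.cell_types == toy_expr.cell_types

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            load_expression(tmp_path / "nope.csv")

    def test_duplicate_gene_name_rejected(self, tmp_path):
        f = tmp_path / "expr.csv"
        f.write_text("cell,G1,G1\nc1,1,2\n")
        with pytest.raises(ValidationError):
            load_expression(f)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            ExpressionMatrix(
                np.array([[1.0, -0.5]]), ["c1"], ["G1", "G2"], ["t"]
            )


class TestLRDatabase:
    def test_load_preserves_order(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text("ligand\treceptor\nL1\tR1\nL2\tR2\n")
        db = load_lr_database(f)
        assert db.pairs == [("L1", "R1"), ("L2", "R2")]

    def test_duplicates_dropped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "db.tsv"
        f.write_text("ligand\treceptor\nL1\tR1\nL1\tR1\n")
        with caplog.at_level("WARNING"):
            db = load_lr_database(f)
        assert len(db) == 1
        assert any("duplicate" in m for m in caplog.messages)

    def test_empty_body_gives_empty_db(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text("ligand\treceptor\n")
        assert len(load_lr_database(f)) == 0

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text("source\ttarget\nL1\tR1\n")
        with pytest.raises(FormatError):
            load_lr_database(f)


class TestBuildCCIM:
    def test_two_cell_worked_example(self):
        # A expresses only the ligand, B only the receptor: the only nonzero
        # score is the directed pair A -> B with 2 * 3 = 6.
        expr = ExpressionMatrix(
            np.array([[2.0, 0.0], [0.0, 3.0]]), ["A", "B"], ["L", "R"], ["t", "t"]
        )
        db = LigandReceptorDB([("L", "R")])
        ccim = build_ccim(expr, db, include_self_pairs=True)
        assert ccim.n_pairs == 4
        lookup = {
            (s, r): v
            for s, r, v in zip(
                ccim.pair_meta["sender_id"], ccim.pair_meta["receiver_id"], ccim.scores[:, 0]
            )
        }
        assert lookup == {("A", "A"): 0, ("A", "B"): 6, ("B", "A"): 0, ("B", "B"): 0}

    @pytest.mark.parametrize("include_self,expected", [(False, 6), (True, 9)])
    def test_pair_count_enumeration(self, toy_expr, toy_db, include_self, expected):
        ccim = build_ccim(toy_expr, toy_db, include_self_pairs=include_self)
        assert ccim.n_pairs == expected

    def test_all_zero_expression_gives_zero_ccim(self):
        expr = ExpressionMatrix(
            np.zeros((3, 2)), ["a", "b", "c"], ["L", "R"], ["t"] * 3
        )
        ccim = build_ccim(expr, LigandReceptorDB([("L", "R")]))
        assert np.all(ccim.scores == 0)

    def test_scores_match_brute_force_product(self, rng):
        n_cells, n_genes = 5, 8
        values = rng.uniform(0, 4, size=(n_cells, n_genes))
        ids = [f"c{i}" for i in range(n_cells)]
        genes = [f"g{j}" for j in range(n_genes)]
        expr = ExpressionMatrix(values, ids, genes, ["t"] * n_cells)
        db = LigandReceptorDB([("g0", "g1"), ("g2", "g5"), ("g7", "g3")])
        ccim = build_ccim(expr, db)
        gi = {g: j for j, g in enumerate(genes)}
        ci = {c: i for i, c in enumerate(ids)}
        for row in range(ccim.n_pairs):
            s = ci[ccim.pair_meta["sender_id"][row]]
            r = ci[ccim.pair_meta["receiver_id"][row]]
            for k, (lig, rec) in enumerate(db.pairs):
                assert ccim.scores[row, k] == pytest.approx(
                    values[s, gi[lig]] * values[r, gi[rec]], abs=0
                )

    def test_missing_genes_dropped_and_empty_feature_space_raises(self, toy_expr):
        db = LigandReceptorDB([("L1", "R1"), ("ABSENT", "R1")])
        ccim = build_ccim(toy_expr, db)
        assert ccim.n_features == 1
        with pytest.raises(EmptyFeatureSpaceError):
            build_ccim(toy_expr, LigandReceptorDB([("ABSENT", "R1")]))

    def test_sender_receiver_subsets(self, toy_expr, toy_db):
        ccim = build_ccim(toy_expr, toy_db, senders=["A"], receivers=["B", "C"])
        assert list(ccim.pair_meta["sender_id"]) == ["A", "A"]
        assert list(ccim.pair_meta["receiver_id"]) == ["B", "C"]

    def test_self_pair_exclusion_can_empty_pair_set(self, toy_expr, toy_db):
        with pytest.raises(EmptyPairSetError):
            build_ccim(
                toy_expr, toy_db, include_self_pairs=False, senders=["A"], receivers=["A"]
            )


class TestFilterAndStandardize:
    def test_zero_column_removed_any_positive_threshold(self):
        scores = np.column_stack([np.zeros(10), np.arange(10.0)])
        ccim = make_ccim(scores)
        out = filter_active_features(ccim, min_nonzero_fraction=0.01)
        assert out.n_features == 1
        assert out.feature_meta["ligand"].tolist() == ["L1"]

    def test_threshold_zero_only_removes_constant_columns(self):
        scores = np.column_stack([np.full(10, 2.0), np.arange(10.0)])
        out = filter_active_features(make_ccim(scores), min_nonzero_fraction=0.0)
        assert out.n_features == 1

    def test_counts_by_construction(self, rng):
        # 7 dense active columns + 3 columns nonzero in fewer than 10% of rows
        n = 100
        active = rng.normal(size=(n, 7)) + 5
        sparse = np.zeros((n, 3))
        sparse[:5, :] = 1.0
        ccim = make_ccim(np.hstack([active, sparse]))
        out = filter_active_features(ccim, min_nonzero_fraction=0.1)
        assert out.n_features == 7
        assert out.feature_meta["ligand"].tolist() == [f"L{j}" for j in range(7)]

    def test_all_removed_raises(self):
        with pytest.raises(EmptyFeatureSpaceError):
            filter_active_features(make_ccim(np.zeros((5, 3))), min_nonzero_fraction=0.5)

    def test_zscore_properties_and_idempotence(self):
        ccim = make_ccim(np.array([[1.0], [2.0], [3.0]]))
        out = standardize_features(ccim)
        assert out.standardized
        assert out.scores.mean() == pytest.approx(0, abs=1e-12)
        assert out.scores.std() == pytest.approx(1, abs=1e-12)
        again = standardize_features(out)
        np.testing.assert_allclose(again.scores, out.scores, atol=1e-10)

    def test_constant_column_raises_named_error(self):
        ccim = make_ccim(np.column_stack([np.ones(4), np.arange(4.0)]))
        with pytest.raises(ConstantFeatureError, match="L0"):
            standardize_features(ccim)

    def test_filter_then_standardize_is_finite(self, rng):
        scores = rng.poisson(0.5, size=(50, 20)).astype(float)
        ccim = make_ccim(scores)
        out = standardize_features(filter_active_features(ccim, 0.05))
        assert np.isfinite(out.scores).all()
        np.testing.assert_allclose(out.scores.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.scores.std(axis=0), 1, atol=1e-6)


class TestCCIMIO:
    @pytest.mark.parametrize("fmt", ["csv", "mtx"])
    def test_round_trip(self, random_ccim, tmp_path, fmt):
        write_ccim(random_ccim, tmp_path / "ccim", format=fmt)
        back = read_ccim(tmp_path / "ccim")
        np.testing.assert_allclose(back.scores, random_ccim.scores, atol=1e-12)
        pd.testing.assert_frame_equal(back.pair_meta, random_ccim.pair_meta)
        pd.testing.assert_frame_equal(back.feature_meta, random_ccim.feature_meta)
        assert back.standardized == random_ccim.standardized

    def test_truncated_sidecar_raises(self, random_ccim, tmp_path):
        write_ccim(random_ccim, tmp_path / "ccim")
        pairs = (tmp_path / "ccim" / "pairs.tsv").read_text().splitlines()
        (tmp_path / "ccim" / "pairs.tsv").write_text("\n".join(pairs[:5]) + "\n")
        with pytest.raises(FormatError):
            read_ccim(tmp_path / "ccim")

    def test_empty_ccim_write_refused(self, tmp_path):
        ccim = make_ccim(np.empty((0, 3)))
        with pytest.raises(EmptyPairSetError):
            write_ccim(ccim, tmp_path / "ccim")
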