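"""Construction and IO of cell-cell interaction matrices (CCIMs).

A CCIM records, for every ordered (sender, receiver) pair of single cells,
an interaction score for each ligand-receptor feature.  The score convention
is the single-cell-resolution one popularized by NICHES: the ligand's
expression in the sender multiplied by the cognate receptor's expression in
the receiver, so that a feature is "on" for a pair only when both partners
express their respective gene.

The module also handles reading expression matrices and ligand-receptor
databases from plain-text formats, activity filtering, and per-feature
z-scoring (boosting downstream assumes standardized design columns).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    ConstantFeatureError,
    EmptyFeatureSpaceError,
    EmptyPairSetError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PAIR_META_COLUMNS = ["sender_id", "receiver_id", "sender_type", "receiver_type"]
FEATURE_META_COLUMNS = ["ligand", "receptor"]


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of nonnegative expression values with labels.

    Parameters
    ----------
    values
        Dense array of shape (n_cells, n_genes); entries must be >= 0
        (normalized values or counts, normalization is assumed upstream).
    cell_ids, gene_ids
        Unique row/column names, order preserved from the source file.
    cell_types
        One label per cell.
    spatial_coords
        Optional (n_cells, 2) coordinates, passed through as metadata only.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_types: list[str]
    spatial_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2D matrix")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValidationError("cell/gene id lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if len(self.cell_types) != n:
            raise ValidationError("cell_types length must equal number of cells")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")
        if self.spatial_coords is not None:
            self.spatial_coords = np.asarray(self.spatial_coords, dtype=float)
            if self.spatial_coords.shape != (n, 2):
                raise ValidationError("spatial_coords must have shape (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LigandReceptorDB:
    """Ordered list of unique (ligand gene, receptor gene) pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("ligand-receptor pairs must be unique")
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValidationError("empty gene name in ligand-receptor pair")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CCIM:
    """Cell pairs x ligand-receptor features interaction score matrix.

    ``pair_meta`` has one row per matrix row with columns
    (sender_id, receiver_id, sender_type, receiver_type); ``feature_meta``
    has one row per matrix column with columns (ligand, receptor).
    """

    scores: np.ndarray
    pair_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2D matrix")
        if len(self.pair_meta) != self.scores.shape[0]:
            raise ValidationError("pair_meta row count does not match scores")
        if len(self.feature_meta) != self.scores.shape[1]:
            raise ValidationError("feature_meta row count does not match scores")
        missing = [c for c in PAIR_META_COLUMNS if c not in self.pair_meta.columns]
        if missing:
            raise ValidationError(f"pair_meta missing columns: {missing}")
        missing = [c for c in FEATURE_META_COLUMNS if c not in self.feature_meta.columns]
        if missing:
            raise ValidationError(f"feature_meta missing columns: {missing}")
        feats = list(zip(self.feature_meta["ligand"], self.feature_meta["receptor"]))
        if len(set(feats)) != len(feats):
            raise ValidationError("duplicate ligand-receptor features")

    @property
    def n_pairs(self) -> int:
        return self.scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]

    def feature_names(self) -> list[str]:
        return [
            f"{lig}::{rec}"
            for lig, rec in zip(self.feature_meta["ligand"], self.feature_meta["receptor"])
        ]


# ---------------------------------------------------------------------------
# expression IO


def _read_cell_types(path: str | Path, cell_ids: Sequence[str]) -> list[str]:
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise FormatError("cell-type table needs two columns (cell_id, cell_type)")
    mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise FormatError(f"cell-type table missing {len(missing)} cells, e.g. {missing[0]!r}")
    return [mapping[c] for c in cell_ids]


def load_expression(
    path: str | Path,
    format: str = "csv",
    cell_types_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix (cells in rows, genes in columns).

    ``format`` is one of ``csv``, ``tsv`` (header row of gene names, index
    column of cell ids) or ``mtx_triplet`` (MatrixMarket file with companion
    ``<path>.rows`` / ``<path>.cols`` name files).  A cell-type table
    (2-column TSV) may accompany any format; without one every cell is
    labelled ``"unspecified"``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"expression file not found: {path}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):  # pandas silently renames dupes
            raise ValidationError(f"duplicate gene names in {path}")
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif format == "mtx_triplet":
        rows_file = path.with_suffix(path.suffix + ".rows")
        cols_file = path.with_suffix(path.suffix + ".cols")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise IOError(f"companion name file not found: {f}")
        values = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
        cell_ids = rows_file.read_text().split()
        gene_ids = cols_file.read_text().split()
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    if cell_types_path is not None:
        cell_types = _read_cell_types(cell_types_path, cell_ids)
    else:
        cell_types = ["unspecified"] * len(cell_ids)
    return ExpressionMatrix(values, cell_ids, gene_ids, cell_types)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write an expression matrix; inverse of :func:`load_expression`."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
        df.to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        path.with_suffix(path.suffix + ".rows").write_text("\n".join(expr.cell_ids) + "\n")
        path.with_suffix(path.suffix + ".cols").write_text("\n".join(expr.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def write_cell_types(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame({"cell_id": expr.cell_ids, "cell_type": expr.cell_types}).to_csv(
        path, sep="\t", index=False
    )


def load_lr_database(path: str | Path) -> LigandReceptorDB:
    """Read a ligand-receptor database TSV with columns ``ligand``/``receptor``.

    Duplicated (ligand, receptor) rows are dropped, keeping first occurrence,
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"ligand-receptor database not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in FEATURE_META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"ligand-receptor database missing column {col!r}")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lig, rec in zip(df["ligand"], df["receptor"]):
        pair = (str(lig), str(rec))
        if pair in seen:
            n_dup += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    if n_dup:
        logger.warning("dropped %d duplicated ligand-receptor pairs", n_dup)
    return LigandReceptorDB(pairs)


# ---------------------------------------------------------------------------
# CCIM construction

ScoreKernel = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _product_kernel(ligand: np.ndarray, receptor: np.ndarray) -> np.ndarray:
    return ligand * receptor


def build_ccim(
    expr: ExpressionMatrix,
    db: LigandReceptorDB,
    include_self_pairs: bool = True,
    senders: Sequence[str] | None = None,
    receivers: Sequence[str] | None = None,
    kernel: ScoreKernel = _product_kernel,
) -> CCIM:
    """Construct a CCIM from expression data and a ligand-receptor database.

    One row per ordered (sender, receiver) pair drawn from the requested
    cell subsets (all cells by default); ``score(s, r, k) =
    kernel(expr[s, ligand_k], expr[r, receptor_k])`` with the default kernel
    being the product.  Pairs whose ligand or receptor gene is absent from
    the expression matrix are dropped with a warning.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    kept: list[tuple[str, str]] = []
    lig_idx: list[int] = []
    rec_idx: list[int] = []
    for lig, rec in db.pairs:
        if lig in gene_index and rec in gene_index:
            kept.append((lig, rec))
            lig_idx.append(gene_index[lig])
            rec_idx.append(gene_index[rec])
    n_dropped = len(db.pairs) - len(kept)
    if n_dropped:
        logger.warning("dropped %d ligand-receptor pairs with genes absent from data", n_dropped)
    if not kept:
        raise EmptyFeatureSpaceError("no ligand-receptor pair maps into the expression data")

    cell_index = {c: i for i, c in enumerate(expr.cell_ids)}

    def _resolve(subset: Sequence[str] | None) -> list[str]:
        if subset is None:
            return list(expr.cell_ids)
        unknown = [c for c in subset if c not in cell_index]
        if unknown:
            raise ValidationError(f"unknown cell ids: {unknown[:3]}")
        return list(subset)

    sender_ids = _resolve(senders)
    receiver_ids = _resolve(receivers)
    pairs = [
        (s, r)
        for s in sender_ids
        for r in receiver_ids
        if include_self_pairs or s != r
    ]
    if not pairs:
        raise EmptyPairSetError("no (sender, receiver) pairs retained")

    s_rows = np.array([cell_index[s] for s, _ in pairs])
    r_rows = np.array([cell_index[r] for _, r in pairs])
    L = expr.values[np.ix_(s_rows, lig_idx)]  # pairs are row-aligned below
    R = expr.values[np.ix_(r_rows, rec_idx)]
    scores = kernel(L, R)

    type_of = dict(zip(expr.cell_ids, expr.cell_types))
    pair_meta = pd.DataFrame(
        {
            "sender_id": [s for s, _ in pairs],
            "receiver_id": [r for _, r in pairs],
            "sender_type": [type_of[s] for s, _ in pairs],
            "receiver_type": [type_of[r] for _, r in pairs],
        }
    )
    feature_meta = pd.DataFrame(kept, columns=FEATURE_META_COLUMNS)
    return CCIM(scores, pair_meta, feature_meta, standardized=False)


def filter_active_features(ccim: CCIM, min_nonzero_fraction: float = 0.05) -> CCIM:
    """Keep features that are active: nonzero often enough and non-constant.

    A feature is retained when its fraction of nonzero scores is at least
    ``min_nonzero_fraction`` and its variance is strictly positive.
    """
    if ccim.standardized:
        raise ValidationError("filter_active_features expects an unstandardized CCIM")
    if not 0 <= min_nonzero_fraction <= 1:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    nonzero_frac = (ccim.scores != 0).mean(axis=0)
    variances = ccim.scores.var(axis=0)
    keep = (nonzero_frac >= min_nonzero_fraction) & (variances > 0)
    if not keep.any():
        raise EmptyFeatureSpaceError("all features removed by activity filter")
    return CCIM(
        ccim.scores[:, keep],
        ccim.pair_meta.reset_index(drop=True),
        ccim.feature_meta.loc[keep].reset_index(drop=True),
        standardized=False,
    )


def standardize_features(ccim: CCIM, ddof: int = 0) -> CCIM:
    """Z-score every feature column (population SD by default)."""
    sd = ccim.scores.std(axis=0, ddof=ddof)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        lig = ccim.feature_meta["ligand"].iloc[constant[0]]
        rec = ccim.feature_meta["receptor"].iloc[constant[0]]
        raise ConstantFeatureError(
            f"feature {lig}::{rec} is constant; run filter_active_features first"
        )
    scores = (ccim.scores - ccim.scores.mean(axis=0)) / sd
    return CCIM(
        scores,
        ccim.pair_meta.reset_index(drop=True),
        ccim.feature_meta.reset_index(drop=True),
        standardized=True,
    )


# ---------------------------------------------------------------------------
# CCIM IO (directory with scores + metadata sidecars)


def write_ccim(ccim: CCIM, path: str | Path, format: str = "csv") -> None:
    """Write a CCIM to a directory: scores + pairs.tsv + features.tsv + meta.json."""
    if ccim.n_pairs == 0:
        raise EmptyPairSetError("refusing to write a CCIM with zero pairs")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        pd.DataFrame(ccim.scores, columns=ccim.feature_names()).to_csv(
            path / "scores.csv", index=False
        )
    elif format == "mtx":
        scipy.io.mmwrite(str(path / "scores.mtx"), scipy.sparse.coo_matrix(ccim.scores))
    else:
        raise ValueError(f"unknown CCIM format: {format!r}")
    ccim.pair_meta.to_csv(path / "pairs.tsv", sep="\t", index=False)
    ccim.feature_meta.to_csv(path / "features.tsv", sep="\t", index=False)
    meta = {
        "standardized": bool(ccim.standardized),
        "n_pairs": int(ccim.n_pairs),
        "n_features": int(ccim.n_features),
        "format": format,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_ccim(path: str | Path) -> CCIM:
    """Read a CCIM written by :func:`write_ccim`."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise IOError(f"not a CCIM directory (missing meta.json): {path}")
    meta = json.loads(meta_file.read_text())
    if meta.get("format", "csv") == "csv":
        scores = pd.read_csv(path / "scores.csv").to_numpy(dtype=float)
    else:
        scores = np.asarray(scipy.io.mmread(path / "scores.mtx").todense(), dtype=float)
    pair_meta = pd.read_csv(path / "pairs.tsv", sep="\t", dtype=str)
    feature_meta = pd.read_csv(path / "features.tsv", sep="\t", dtype=str)
    if len(pair_meta) != scores.shape[0] or len(feature_meta) != scores.shape[1]:
        raise FormatError(
            f"metadata/matrix dimension mismatch in {path}: scores {scores.shape}, "
            f"{len(pair_meta)} pairs, {len(feature_meta)} features"
        )
    try:
        return CCIM(scores, pair_meta, feature_meta, standardized=bool(meta["standardized"]))
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc
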