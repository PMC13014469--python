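"""Synthetic fixtures with planted structure, plus recovery metrics.

The planted CCIM emulates the regime the model assumes: K groups of cell
pairs, each elevated by a fixed effect on its own disjoint block of
ligand-receptor features, plus i.i.d. Gaussian noise.  Scores are simulated
directly on the (post-standardization) real-valued scale rather than through
a count model, because that is the input regime of the autoencoder.  Sender
and receiver cell types are synthesized to coincide with the planted group,
so type-colored visualizations are testable.

Also provided: a planted expression-level generator (cell-type programs of
ligand/receptor means, so CCIM construction itself can be exercised end to
end), the adjusted Rand index, and top-k signature precision/recall for the
ranked interaction lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ccim import CCIM, ExpressionMatrix, LigandReceptorDB
from .errors import ShapeError, SpecError


@dataclass
class PlantedCCIMSpec:
    """Parameters of the planted-cluster CCIM benchmark.

    Defaults define the reference benchmark: 4 clusters of 200 cell pairs
    over 40 features with disjoint 3-feature signatures, effect size 3 on
    unit-variance noise.
    """

    k_clusters: int = 4
    n_pairs_per_cluster: int = 200
    n_features: int = 40
    signature_size: int = 3
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.k_clusters < 1 or self.n_pairs_per_cluster < 1:
            raise SpecError("cluster count and pairs per cluster must be >= 1")
        if self.signature_size < 1:
            raise SpecError("signature_size must be >= 1")
        if self.k_clusters * self.signature_size > self.n_features:
            raise SpecError("disjoint signatures need k*signature_size <= n_features")
        if self.effect_size <= 0:
            raise SpecError("effect_size must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted labels (one per pair) and per-cluster signature feature sets."""

    labels: np.ndarray
    signatures: list[list[int]]

    def __post_init__(self) -> None:
        flat = [j for sig in self.signatures for j in sig]
        if len(flat) != len(set(flat)):
            raise SpecError("signatures must be pairwise disjoint")


def generate_ccim(spec: PlantedCCIMSpec) -> tuple[CCIM, GroundTruth]:
    """Simulate a CCIM with planted cluster structure.

    scores[i, j] = effect_size * 1[j in signature(label_i)] + Normal(0, sd).
    Cluster c occupies the contiguous feature block
    [c*signature_size, (c+1)*signature_size).  Sender/receiver types encode
    the planted label.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.k_clusters * spec.n_pairs_per_cluster
    labels = np.repeat(np.arange(spec.k_clusters), spec.n_pairs_per_cluster)
    scores = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    signatures: list[list[int]] = []
    for c in range(spec.k_clusters):
        block = list(range(c * spec.signature_size, (c + 1) * spec.signature_size))
        signatures.append(block)
        scores[np.ix_(labels == c, block)] += spec.effect_size
    pair_meta = pd.DataFrame(
        {
            "sender_id": [f"s{i:05d}" for i in range(n)],
            "receiver_id": [f"r{i:05d}" for i in range(n)],
            "sender_type": [f"senderType{c + 1}" for c in labels],
            "receiver_type": [f"receiverType{c + 1}" for c in labels],
        }
    )
    feature_meta = pd.DataFrame(
        {
            "ligand": [f"L{j:03d}" for j in range(spec.n_features)],
            "receptor": [f"R{j:03d}" for j in range(spec.n_features)],
        }
    )
    ccim = CCIM(scores, pair_meta, feature_meta, standardized=False)
    return ccim, GroundTruth(labels, signatures)


def generate_expression(
    n_cells: int,
    cell_type_programs: dict[str, dict[str, float]],
    db: LigandReceptorDB,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ExpressionMatrix:
    """Simulate expression from per-type mean programs.

    ``cell_type_programs`` maps cell type -> {gene: mean expression}; genes
    of the ligand-receptor database absent from a program default to mean 0.
    Cells are assigned types round-robin; values are Normal(mean, noise_sd)
    truncated at zero.  Deterministic given ``seed``.
    """
    if not cell_type_programs:
        raise SpecError("at least one cell-type program required")
    if n_cells < len(cell_type_programs):
        raise SpecError("need at least one cell per type")
    for t, prog in cell_type_programs.items():
        if not isinstance(prog, dict):
            raise SpecError(f"program for type {t!r} must map gene -> mean")
        for g, mu in prog.items():
            if mu < 0:
                raise SpecError(f"negative mean for gene {g!r} in type {t!r}")
    genes: list[str] = []
    for lig, rec in db.pairs:
        for g in (lig, rec):
            if g not in genes:
                genes.append(g)
    for prog in cell_type_programs.values():
        for g in prog:
            if g not in genes:
                genes.append(g)
    types = list(cell_type_programs)
    cell_types = [types[i % len(types)] for i in range(n_cells)]
    means = np.array(
        [[cell_type_programs[t].get(g, 0.0) for g in genes] for t in cell_types]
    )
    rng = np.random.default_rng(seed)
    values = np.maximum(means + rng.normal(0.0, noise_sd, size=means.shape), 0.0)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    return ExpressionMatrix(values, cell_ids, genes, cell_types)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two clusterings (1 identical, ~0 chance)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ShapeError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def match_clusters_to_truth(
    assigned: np.ndarray, truth_labels: np.ndarray
) -> dict[int, int]:
    """Greedy one-to-one matching of predicted clusters to planted clusters.

    Pairs are taken in decreasing order of overlap (number of observations
    shared); returns {true cluster id -> predicted cluster id} for the true
    clusters that obtained a match.
    """
    assigned = np.asarray(assigned)
    truth_labels = np.asarray(truth_labels)
    if assigned.shape != truth_labels.shape:
        raise ShapeError("labelings must have equal length")
    overlaps: list[tuple[int, int, int]] = []
    for t in np.unique(truth_labels):
        mask = truth_labels == t
        for c in np.unique(assigned[mask]):
            overlaps.append((int(np.sum(assigned[mask] == c)), int(t), int(c)))
    overlaps.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched: dict[int, int] = {}
    used: set[int] = set()
    for _, t, c in overlaps:
        if t in matched or c in used:
            continue
        matched[t] = c
        used.add(c)
    return matched


def feature_recovery(
    lists: dict[int, pd.DataFrame],
    assigned: np.ndarray,
    truth: GroundTruth,
    top_k: int,
) -> tuple[float, float]:
    """Top-k precision/recall of ranked features against planted signatures.

    Predicted clusters are matched to planted clusters greedily by label
    overlap; for each planted cluster the top-k entries of its matched
    cluster's ranked list are compared with the planted signature.  Planted
    clusters without a match, or with an empty list, contribute precision
    and recall 0.  Returns (mean precision, mean recall) over planted
    clusters.
    """
    if top_k < 1:
        raise SpecError("top_k must be >= 1")
    matched = match_clusters_to_truth(np.asarray(assigned), truth.labels)
    precisions: list[float] = []
    recalls: list[float] = []
    for t, signature in enumerate(truth.signatures):
        cluster = matched.get(t)
        ranked = lists.get(cluster) if cluster is not None else None
        if ranked is None or len(ranked) == 0:
            precisions.append(0.0)
            recalls.append(0.0)
            continue
        top = set(ranked["feature"].to_numpy()[:top_k].astype(int))
        hits = len(top & set(signature))
        precisions.append(hits / top_k)
        recalls.append(hits / len(signature))
    return float(np.mean(precisions)), float(np.mean(recalls))


def write_truth(truth: GroundTruth, out_dir) -> None:
    """Write truth_labels.tsv and truth_signatures.tsv next to a CCIM."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"pair": np.arange(len(truth.labels)), "label": truth.labels}).to_csv(
        out_dir / "truth_labels.tsv", sep="\t", index=False
    )
    rows = [
        {"cluster": c, "feature": j}
        for c, sig in enumerate(truth.signatures)
        for j in sig
    ]
    pd.DataFrame(rows).to_csv(out_dir / "truth_signatures.tsv", sep="\t", index=False)


def read_truth(out_dir) -> GroundTruth:
    from pathlib import Path

    out_dir = Path(out_dir)
    labels = pd.read_csv(out_dir / "truth_labels.tsv", sep="\t")["label"].to_numpy()
    sig_table = pd.read_csv(out_dir / "truth_signatures.tsv", sep="\t")
    signatures = [
        sig_table.loc[sig_table["cluster"] == c, "feature"].astype(int).tolist()
        for c in sorted(sig_table["cluster"].unique())
    ]
    return GroundTruth(labels, signatures)
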