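"""Interpretation of a trained model: cluster assignments, ranked
ligand-receptor lists, 2D embeddings and file/plot exports.

Cluster indexing convention (fixed and documented here, used everywhere):
clusters are numbered 1..2d; cluster c in 1..d is the positive-sign cluster
of latent dimension c, cluster c in d+1..2d is the negative-sign cluster of
dimension c-d.  :func:`cluster_to_dimension` maps between the two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ccim import CCIM
from .errors import InputSizeError, ValidationError
from .model import TrainedModel


def cluster_to_dimension(cluster_index: int, d: int) -> tuple[int, int]:
    """Map a 1-based cluster index in 1..2d to (1-based dimension, sign)."""
    if not 1 <= cluster_index <= 2 * d:
        raise ValueError(f"cluster index {cluster_index} outside 1..{2 * d}")
    if cluster_index <= d:
        return cluster_index, +1
    return cluster_index - d, -1


def assign_clusters(P: np.ndarray) -> pd.DataFrame:
    """Hard assignment: per row the argmax cluster and its probability.

    Ties break toward the lowest cluster index.  Because softmax is strictly
    monotone, the argmax over probabilities equals the argmax over the
    pre-softmax split activations.  Returns a DataFrame with 1-based
    ``cluster`` and ``probability`` columns.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("P is not a row-stochastic probability matrix")
    idx = P.argmax(axis=1)
    return pd.DataFrame(
        {"cluster": idx + 1, "probability": P[np.arange(P.shape[0]), idx]}
    )


def rank_interactions(
    B: np.ndarray, cluster_index: int, feature_meta: pd.DataFrame
) -> pd.DataFrame:
    """Ranked ligand-receptor interactions characterizing one cluster.

    Takes the encoder-weight row of the cluster's latent dimension, keeps
    the entries whose sign matches the cluster (strictly positive for a
    positive-sign cluster, strictly negative — in absolute value — for a
    negative-sign one), min-max normalizes those magnitudes to importance
    scores in [0, 1] and sorts descending.  Zero weights are unselected
    features and never appear; a single selected feature gets importance 1.
    Columns: rank, feature (column index), ligand, receptor, importance,
    raw_weight.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    d = B.shape[0]
    dim, sign = cluster_to_dimension(cluster_index, d)
    row = B[dim - 1]
    idx = np.flatnonzero(row > 0) if sign > 0 else np.flatnonzero(row < 0)
    magnitudes = np.abs(row[idx])
    order = np.argsort(-magnitudes, kind="stable")
    idx, magnitudes = idx[order], magnitudes[order]
    if len(idx) == 0:
        importance = np.empty(0)
    elif len(idx) == 1 or magnitudes[0] == magnitudes[-1]:
        importance = np.ones(len(idx))
    else:
        importance = (magnitudes - magnitudes.min()) / (magnitudes.max() - magnitudes.min())
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(idx) + 1),
            "feature": idx,
            "ligand": feature_meta["ligand"].to_numpy()[idx] if len(idx) else [],
            "receptor": feature_meta["receptor"].to_numpy()[idx] if len(idx) else [],
            "importance": importance,
            "raw_weight": row[idx],
        }
    )


def rank_all_clusters(
    B: np.ndarray, feature_meta: pd.DataFrame
) -> dict[int, pd.DataFrame]:
    """Ranked interaction lists for every cluster 1..2d (empty ones included)."""
    d = np.atleast_2d(B).shape[0]
    return {c: rank_interactions(B, c, feature_meta) for c in range(1, 2 * d + 1)}


@dataclass
class Embedding2D:
    """UMAP coordinates for the cell pairs, row-aligned with the CCIM."""

    coords: np.ndarray
    n_neighbors: int
    min_dist: float
    seed: int


def compute_embedding(
    M: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> Embedding2D:
    """2D UMAP embedding of the latent representation (or probabilities).

    Delegates to umap-learn with a fixed random state; the contract covers
    shape, finiteness, row-order preservation and within-version seed
    reproducibility only.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < n_neighbors + 1:
        raise InputSizeError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {M.shape[0]}"
        )
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = np.asarray(reducer.fit_transform(M), dtype=float)
    return Embedding2D(coords, n_neighbors, min_dist, seed)


# ---------------------------------------------------------------------------
# exports


def export_results(
    model: TrainedModel,
    ccim: CCIM,
    assignments: pd.DataFrame,
    lists: dict[int, pd.DataFrame],
    embedding: Embedding2D | None,
    out_dir: str | Path,
    plots: bool = True,
    highlight_cluster: int | None = None,
    highlight_feature: int | None = None,
) -> list[Path]:
    """Write tabular results and the standard result figures.

    Tables: ``assignments.tsv`` (pair metadata + cluster + probability),
    ``ranked_interactions.tsv`` (cluster, rank, ligand, receptor,
    importance, raw_weight), ``embedding.tsv``.  Figures (when ``plots``):
    the embedding colored by hard cluster, by sender type, by receiver
    type, by one cluster's membership probability and by one feature's
    scores.  Defaults for the highlighted cluster/feature are the most
    populated cluster and its top-ranked feature.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    assign_table = pd.concat(
        [ccim.pair_meta.reset_index(drop=True), assignments.reset_index(drop=True)],
        axis=1,
    )
    f = out_dir / "assignments.tsv"
    assign_table.to_csv(f, sep="\t", index=False)
    written.append(f)

    ranked = [df.assign(cluster=c) for c, df in sorted(lists.items()) if len(df)]
    ranked_table = (
        pd.concat(ranked, ignore_index=True)[
            ["cluster", "rank", "ligand", "receptor", "importance", "raw_weight"]
        ]
        if ranked
        else pd.DataFrame(
            columns=["cluster", "rank", "ligand", "receptor", "importance", "raw_weight"]
        )
    )
    f = out_dir / "ranked_interactions.tsv"
    ranked_table.to_csv(f, sep="\t", index=False)
    written.append(f)

    if embedding is not None:
        f = out_dir / "embedding.tsv"
        pd.DataFrame(embedding.coords, columns=["umap1", "umap2"]).to_csv(
            f, sep="\t", index=False
        )
        written.append(f)

    if plots and embedding is not None:
        written.extend(
            _plot_panels(
                model, ccim, assignments, lists, embedding, out_dir,
                highlight_cluster, highlight_feature,
            )
        )
    return written


def _categorical_panel(ax, coords, labels, title):
    for lab in pd.unique(labels):
        m = labels == lab
        ax.scatter(coords[m, 0], coords[m, 1], s=6, label=str(lab))
    ax.set_title(title)
    ax.legend(fontsize=6, markerscale=2, loc="best")
    ax.set_xticks([])
    ax.set_yticks([])


def _plot_panels(
    model, ccim, assignments, lists, embedding, out_dir,
    highlight_cluster, highlight_feature,
) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coords
    P = model.cluster_probabilities(ccim.scores)
    if highlight_cluster is None:
        highlight_cluster = int(assignments["cluster"].mode().iloc[0])
    if highlight_feature is None:
        top = lists.get(highlight_cluster)
        highlight_feature = int(top["feature"].iloc[0]) if top is not None and len(top) else 0

    written: list[Path] = []

    def _save(fig, name):
        f = out_dir / name
        fig.savefig(f, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f)

    fig, ax = plt.subplots(figsize=(4, 4))
    _categorical_panel(ax, coords, assignments["cluster"].to_numpy(), "cluster")
    _save(fig, "embedding_by_cluster.png")

    fig, ax = plt.subplots(figsize=(4, 4))
    _categorical_panel(ax, coords, ccim.pair_meta["sender_type"].to_numpy(), "sender type")
    _save(fig, "embedding_by_sender_type.png")

    fig, ax = plt.subplots(figsize=(4, 4))
    _categorical_panel(ax, coords, ccim.pair_meta["receiver_type"].to_numpy(), "receiver type")
    _save(fig, "embedding_by_receiver_type.png")

    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(coords[:, 0], coords[:, 1], s=6, c=P[:, highlight_cluster - 1], cmap="viridis")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(f"cluster {highlight_cluster} probability")
    ax.set_xticks([]); ax.set_yticks([])
    _save(fig, "embedding_by_cluster_probability.png")

    fig, ax = plt.subplots(figsize=(4, 4))
    name = ccim.feature_names()[highlight_feature]
    sc = ax.scatter(
        coords[:, 0], coords[:, 1], s=6, c=ccim.scores[:, highlight_feature], cmap="magma"
    )
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(f"scores: {name}")
    ax.set_xticks([]); ax.set_yticks([])
    _save(fig, "embedding_by_feature_scores.png")

    top = lists.get(highlight_cluster)
    if top is not None and len(top):
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.scatter(np.arange(1, len(top) + 1), top["importance"], s=20)
        for r, (_, row) in enumerate(top.iterrows(), start=1):
            ax.annotate(
                f"{row['ligand']}::{row['receptor']}",
                (r, row["importance"]),
                fontsize=6,
                rotation=45,
            )
        ax.set_xlabel("rank")
        ax.set_ylabel("importance")
        ax.set_title(f"top interactions, cluster {highlight_cluster}")
        _save(fig, "ranked_interactions.png")
    return written
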