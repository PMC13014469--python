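"""The boosting autoencoder with a split-softmax soft-clustering layer.

Architecture: a single-layer linear encoder Z = X B^T (no bias, no
nonlinearity) whose sparse weight matrix B is fitted by componentwise
boosting; a split-softmax layer turning the d latent activations into 2d
soft-cluster membership probabilities; and a decoder mapping those
probabilities back to the p ligand-receptor features.  Encoder and decoder
are optimized jointly: every epoch alternates one (or several) boosting
sweeps on B with gradient-descent steps on the decoder parameters, both
against the same mean-squared reconstruction loss, so feature selection and
reconstruction co-adapt end to end.

The number of soft clusters is always exactly twice the number of latent
dimensions: each dimension contributes a positive-sign and a negative-sign
cluster.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .boosting import BoostingConfig, boosting_update, compute_pseudo_responses
from .ccim import CCIM
from .errors import CompatibilityError, ShapeError, ValidationError
from .nn import MLPDecoder, split_softmax


@dataclass
class TrainConfig:
    """Configuration of a training run.

    d
        Number of latent dimensions; the model exposes 2*d soft clusters.
    epochs
        Training epochs (one boosting sweep + decoder steps each).
    decoder_learning_rate
        Step size for plain gradient descent on the decoder.
    decoder_steps
        Decoder gradient steps per epoch; several steps per boosting sweep
        keep the decoder close to its optimum for the current encoder, which
        makes the boosting pseudo-responses informative.
    decoder_hidden
        Hidden layer widths; empty = single linear layer (default).
    activation
        Hidden-layer activation (tanh/relu/linear); irrelevant when
        ``decoder_hidden`` is empty.
    boosting
        Componentwise-boosting hyperparameters.
    seed
        Seeds the decoder initialization; boosting itself is deterministic.
    """

    d: int = 4
    epochs: int = 250
    decoder_learning_rate: float = 0.1
    decoder_steps: int = 20
    decoder_hidden: tuple[int, ...] = ()
    activation: str = "tanh"
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    seed: int = 0
    batch_mode: str = "full"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.decoder_learning_rate <= 0:
            raise ValueError("decoder_learning_rate must be positive")
        if self.decoder_steps < 1:
            raise ValueError("decoder_steps must be >= 1")
        if self.batch_mode != "full":
            raise ValueError("only full-batch training is supported")
        self.decoder_hidden = tuple(int(h) for h in self.decoder_hidden)
        if isinstance(self.boosting, dict):
            self.boosting = BoostingConfig(**self.boosting)

    @property
    def n_clusters(self) -> int:
        """Soft-cluster count: two (one per sign) per latent dimension."""
        return 2 * self.d

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["decoder_hidden"] = list(self.decoder_hidden)
        return cfg

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        data = dict(data)
        if "boosting" in data and isinstance(data["boosting"], dict):
            data["boosting"] = BoostingConfig(**data["boosting"])
        return cls(**data)


def encode(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Linear encoder: Z = X B^T."""
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    if X.shape[1] != B.shape[1]:
        raise ShapeError(f"X has {X.shape[1]} features but B expects {B.shape[1]}")
    return X @ B.T


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean squared error over all n*p entries."""
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ShapeError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    return float(np.mean((Xhat - X) ** 2))


@dataclass
class TrainedModel:
    """A trained boosting autoencoder: encoder weights, decoder, history."""

    B: np.ndarray
    decoder: MLPDecoder
    config: TrainConfig
    loss_trace: list[float]
    selections_per_epoch: list[int]
    feature_names: list[str] | None = None

    @property
    def d(self) -> int:
        return self.B.shape[0]

    @property
    def n_features(self) -> int:
        return self.B.shape[1]

    @property
    def n_clusters(self) -> int:
        return 2 * self.d

    def encode(self, X: np.ndarray) -> np.ndarray:
        return encode(X, self.B)

    def cluster_probabilities(self, X: np.ndarray) -> np.ndarray:
        return split_softmax(self.encode(X))

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decoder(self.cluster_probabilities(X))

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a checkpoint directory.

        Encoder weights go to ``encoder_weights.tsv`` as sparse
        (dim, feature, weight) triplets, decoder parameters to
        ``decoder.npz``, training history to ``history.tsv`` and the
        configuration (plus matrix sizes) to ``config.yaml``.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = ["dim\tfeature\tweight"]
        for l, j in zip(*np.nonzero(self.B)):
            rows.append(f"{l}\t{j}\t{float(self.B[l, j])!r}")
        (path / "encoder_weights.tsv").write_text("\n".join(rows) + "\n")
        np.savez(path / "decoder.npz", **self.decoder.get_state())
        hist = ["epoch\tloss\tnew_selections"]
        for i, (loss, k) in enumerate(zip(self.loss_trace, self.selections_per_epoch)):
            hist.append(f"{i}\t{float(loss)!r}\t{k}")
        (path / "history.tsv").write_text("\n".join(hist) + "\n")
        meta = {
            "config": self.config.to_dict(),
            "n_features": int(self.n_features),
            "n_clusters": int(self.n_clusters),
            "feature_names": self.feature_names,
        }
        (path / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = yaml.safe_load((path / "config.yaml").read_text())
        config = TrainConfig.from_dict(meta["config"])
        p = int(meta["n_features"])
        B = np.zeros((config.d, p))
        lines = (path / "encoder_weights.tsv").read_text().strip().splitlines()[1:]
        for line in lines:
            l, j, w = line.split("\t")
            B[int(l), int(j)] = float(w)
        decoder = MLPDecoder(
            2 * config.d,
            p,
            config.decoder_hidden,
            config.activation,
            np.random.default_rng(config.seed),
        )
        with np.load(path / "decoder.npz") as state:
            decoder.set_state(dict(state))
        loss_trace: list[float] = []
        selections: list[int] = []
        for line in (path / "history.tsv").read_text().strip().splitlines()[1:]:
            _, loss, k = line.split("\t")
            loss_trace.append(float(loss))
            selections.append(int(k))
        return cls(B, decoder, config, loss_trace, selections, meta.get("feature_names"))


def fit(X: np.ndarray, cfg: TrainConfig) -> TrainedModel:
    """Train the boosting autoencoder on a standardized score matrix.

    Per epoch: (1) compute pseudo-responses at the current state, (2) run
    ``updates_per_epoch`` boosting sweeps on the encoder, (3) take
    ``decoder_steps`` gradient-descent steps on the decoder against the
    reconstruction loss under the updated encoder, (4) record the epoch-end
    loss.  With ``epochs=0`` the encoder stays all-zero and the decoder is
    returned freshly initialized (latent representation identically zero,
    cluster probabilities exactly uniform).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    decoder = MLPDecoder(2 * cfg.d, p, cfg.decoder_hidden, cfg.activation, rng)
    B = np.zeros((cfg.d, p))
    loss_trace: list[float] = []
    selections_per_epoch: list[int] = []

    for _ in range(cfg.epochs):
        n_new = 0
        for _ in range(cfg.boosting.updates_per_epoch):
            U = compute_pseudo_responses(X, B, decoder)
            newly_zero = B == 0
            B, updates = boosting_update(B, X, U, cfg.boosting)
            n_new += int(sum(1 for (l, j, _) in updates if newly_zero[l, j]))
        Z = encode(X, B)
        P = split_softmax(Z)
        for _ in range(cfg.decoder_steps):
            Xhat, cache = decoder.forward(P)
            dXhat = 2.0 * (Xhat - X) / (n * p)
            _, gW, gb = decoder.backward(cache, dXhat)
            decoder.sgd_step(gW, gb, cfg.decoder_learning_rate)
        loss_trace.append(reconstruction_loss(X, decoder(P)))
        selections_per_epoch.append(n_new)

    return TrainedModel(B, decoder, cfg, loss_trace, selections_per_epoch)


def train(ccim: CCIM, cfg: TrainConfig) -> TrainedModel:
    """Train on a CCIM; requires standardized features."""
    if not ccim.standardized:
        raise ValidationError(
            "CCIM is not standardized; run standardize_features first"
        )
    model = fit(ccim.scores, cfg)
    model.feature_names = ccim.feature_names()
    return model


def check_compatible(model: TrainedModel, ccim: CCIM) -> None:
    """Raise CompatibilityError unless the model was trained on this feature space."""
    if model.n_features != ccim.n_features:
        raise CompatibilityError(
            f"model expects {model.n_features} features, CCIM has {ccim.n_features}"
        )
    if model.feature_names is not None:
        names = ccim.feature_names()
        if names != list(model.feature_names):
            raise CompatibilityError("model and CCIM feature names differ")
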