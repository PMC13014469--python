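"""Componentwise L2-boosting of the linear encoder weight matrix.

The encoder of the model is a single linear layer Z = X B^T whose d x p
weight matrix B starts at zero.  Instead of gradient descent, each row of B
(one latent dimension) is fitted by componentwise boosting: the negative
gradient of the reconstruction loss with respect to that latent dimension is
used as a regression pseudo-response, a univariate least-squares fit is
computed for every candidate feature column, and only the single best
feature receives a small (step-size-shrunken) weight update.  Accumulating
these one-feature updates from a zero start yields a sparse weight matrix in
which every latent dimension is characterized by a small, explicit set of
input features.

The optional disentanglement constraint residualizes the pseudo-response of
dimension l against the current activations of all other dimensions before
selection, steering different dimensions toward distinct, largely
uncorrelated signals.  A harder variant masks out features already selected
by other dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoCandidateError, NumericalError, ShapeError
from .nn import MLPDecoder, split_softmax, split_softmax_backward

DISENTANGLEMENT_MODES = ("residualize", "exclude")


@dataclass
class BoostingConfig:
    """Hyperparameters of the componentwise boosting encoder update.

    step_size
        Shrinkage nu in (0, 1] applied to each selected coefficient.
    updates_per_epoch
        Number of boosting sweeps (one selected feature per latent dimension
        per sweep) per training epoch.
    disentanglement
        Whether to constrain feature selection so latent dimensions capture
        distinct signals.
    mode
        "residualize" (project the pseudo-response off the other dimensions'
        activations) or "exclude" (mask features already selected elsewhere).
    epsilon
        Guard added to the denominator of the univariate coefficient.
    """

    step_size: float = 0.1
    updates_per_epoch: int = 1
    disentanglement: bool = True
    mode: str = "residualize"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.step_size <= 1:
            raise ValueError("step_size must be in (0, 1]")
        if self.updates_per_epoch < 1:
            raise ValueError("updates_per_epoch must be >= 1")
        if self.mode not in DISENTANGLEMENT_MODES:
            raise ValueError(f"mode must be one of {DISENTANGLEMENT_MODES}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def compute_pseudo_responses(
    X: np.ndarray, B: np.ndarray, decoder: MLPDecoder
) -> np.ndarray:
    """Negative loss gradients w.r.t. the latent representation (n x d).

    Runs one coherent forward/backward pass X -> Z -> P -> X_hat at the
    current encoder weights and decoder parameters; the reconstruction loss
    is the mean squared error over all n*p entries.  Column l of the result
    is -dL/dz_l, the regression target for boosting latent dimension l.
    """
    n, p = X.shape
    Z = X @ B.T
    P = split_softmax(Z)
    Xhat, cache = decoder.forward(P)
    dXhat = 2.0 * (Xhat - X) / (n * p)
    dP, _, _ = decoder.backward(cache, dXhat)
    U = -split_softmax_backward(Z, P, dP)
    if not np.isfinite(U).all():
        raise NumericalError("non-finite pseudo-responses")
    return U


def select_feature(
    X: np.ndarray,
    u: np.ndarray,
    candidate_mask: np.ndarray | None = None,
    epsilon: float = 1e-12,
) -> tuple[int, float]:
    """Best single feature for a univariate least-squares fit to u.

    For each allowed column j the coefficient beta_j = (x_j^T u) /
    (x_j^T x_j + epsilon) is evaluated; on standardized columns the residual
    sum of squares is minimized by the j maximizing |x_j^T u|.  Ties break
    toward the lowest index.  Returns (index, coefficient).
    """
    X = np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    if X.shape[0] != u.shape[0]:
        raise ShapeError("design and response lengths differ")
    p = X.shape[1]
    if candidate_mask is None:
        candidate_mask = np.ones(p, dtype=bool)
    if not candidate_mask.any():
        raise NoCandidateError("empty candidate feature set")
    corr = np.abs(X.T @ u)
    corr[~candidate_mask] = -np.inf
    j = int(np.argmax(corr))  # argmax takes the first (lowest) index on ties
    xj = X[:, j]
    beta = float(xj @ u / (xj @ xj + epsilon))
    return j, beta


def residualize(u: np.ndarray, Z_other: np.ndarray) -> np.ndarray:
    """Remove from u its least-squares projection onto span(1, Z_other).

    With no columns in ``Z_other`` the response is returned unchanged;
    rank-deficient designs are handled by the least-squares solver (minimum
    norm solution), never by raising.
    """
    u = np.asarray(u, dtype=float)
    Z_other = np.asarray(Z_other, dtype=float)
    if Z_other.ndim == 1:
        Z_other = Z_other[:, None]
    if Z_other.size == 0 or Z_other.shape[1] == 0:
        return u.copy()
    A = np.column_stack([np.ones(u.shape[0]), Z_other])
    coef, *_ = np.linalg.lstsq(A, u, rcond=None)
    return u - A @ coef


def boosting_update(
    B: np.ndarray,
    X: np.ndarray,
    U: np.ndarray,
    cfg: BoostingConfig,
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """One boosting sweep: per latent dimension, update one encoder weight.

    For each dimension l (in order) the pseudo-response column U[:, l] is
    mean-centered, optionally residualized against the *current* activations
    of the other dimensions (recomputed as rows of B change within the
    sweep), rescaled to unit standard deviation so the step size acts on a
    scale-free response, and handed to :func:`select_feature`.  The selected
    coefficient, shrunken by the step size, is added to B[l, j*].

    Returns the updated copy of B and the list of (dimension, feature,
    increment) updates actually applied.  Dimensions whose processed
    response is numerically constant are skipped, so at most one weight
    entry changes per dimension per call.
    """
    B = np.array(B, dtype=float, copy=True)
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    d, p = B.shape
    if X.shape[1] != p or U.shape != (X.shape[0], d):
        raise ShapeError(
            f"inconsistent shapes: B {B.shape}, X {X.shape}, U {U.shape}"
        )
    updates: list[tuple[int, int, float]] = []
    for l in range(d):
        u = U[:, l] - U[:, l].mean()
        mask = np.ones(p, dtype=bool)
        if cfg.disentanglement and d > 1:
            if cfg.mode == "residualize":
                Z_other = np.delete(X @ B.T, l, axis=1)
                u = residualize(u, Z_other)
            else:  # exclude
                taken = np.zeros(p, dtype=bool)
                for m in range(d):
                    if m != l:
                        taken |= B[m] != 0
                own = B[l] != 0
                mask = (~taken) | own
                if not mask.any():
                    continue
        sd = u.std()
        if sd < 1e-12:
            continue
        u = u / sd
        j, beta = select_feature(X, u, mask, epsilon=cfg.epsilon)
        increment = cfg.step_size * beta
        if increment != 0.0:
            B[l, j] += increment
            updates.append((l, j, increment))
    return B, updates
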