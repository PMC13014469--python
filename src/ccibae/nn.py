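"""Small NumPy neural-network pieces: split-softmax and the decoder MLP.

The split-softmax maps a d-dimensional latent activation vector z to a
2d-dimensional probability vector: the positive parts max(z, 0) and negative
parts max(-z, 0) are concatenated and passed through a softmax.  Each of the
2d output dimensions acts as a soft cluster, so one latent dimension can
host two distinct groups of observations (one per sign) without the softmax
squashing negative activations toward zero.

The decoder is a fully connected network that maps the 2d split-softmax
representation back to the p-dimensional feature space.  It is implemented
directly in NumPy with hand-written backpropagation: the model is tiny
(full-batch, desk-scale) and an explicit backward pass is also what the
componentwise-boosting step needs to build its pseudo-responses.
"""

from __future__ import annotations

import numpy as np

from .errors import NumericalError, ShapeError

_ACTIVATIONS = ("tanh", "relu", "linear")


def split_softmax(Z: np.ndarray) -> np.ndarray:
    """Map latent activations (n x d) to cluster probabilities (n x 2d).

    Per row: s = [max(z, 0), max(-z, 0)], P = softmax(s) with max-subtraction
    for numerical stability.  A zero activation row yields the exactly
    uniform distribution 1/(2d).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.isfinite(Z).all():
        raise NumericalError("non-finite latent activations")
    S = np.concatenate([np.maximum(Z, 0.0), np.maximum(-Z, 0.0)], axis=1)
    S -= S.max(axis=1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=1, keepdims=True)


def split_softmax_backward(Z: np.ndarray, P: np.ndarray, dP: np.ndarray) -> np.ndarray:
    """Gradient of a scalar loss w.r.t. Z, given dL/dP at P = split_softmax(Z).

    The split uses the subgradient convention that BOTH parts are active at
    z = 0 (d max(z,0)/dz = 1[z >= 0], d max(-z,0)/dz = -1[z <= 0]), so the
    all-zero initialization still produces informative gradients instead of
    a dead zone.
    """
    d = Z.shape[1]
    dS = P * (dP - (dP * P).sum(axis=1, keepdims=True))
    return dS[:, :d] * (Z >= 0) - dS[:, d:] * (Z <= 0)


class MLPDecoder:
    """Fully connected decoder with manual forward/backward passes.

    Hidden layers use ``activation`` (tanh by default); the output layer is
    always linear.  An empty ``hidden`` tuple gives a single linear layer,
    the default configuration: reconstruction from cluster probabilities is
    then a learned cluster-profile matrix, which keeps the gradients that
    drive boosting feature selection well behaved.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        hidden: tuple[int, ...] = (),
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
    ):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        rng = rng if rng is not None else np.random.default_rng()
        dims = [in_dim] + list(hidden) + [out_dim]
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.hidden = tuple(hidden)
        self.activation = activation
        self.W = [
            rng.normal(0.0, 1.0 / np.sqrt(dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    # -- forward / backward -------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            return np.tanh(z)
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        return z

    def _act_grad(self, a: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            return 1.0 - a**2
        if self.activation == "relu":
            return (a > 0).astype(float)
        return np.ones_like(a)

    def forward(self, P: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (output, cache) where cache holds layer activations."""
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[1] != self.in_dim:
            raise ShapeError(
                f"decoder expects input width {self.in_dim}, got {P.shape}"
            )
        a = P
        cache = [a]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = z if i == last else self._act(z)
            cache.append(a)
        return a, cache

    def __call__(self, P: np.ndarray) -> np.ndarray:
        return self.forward(P)[0]

    def backward(
        self, cache: list[np.ndarray], dout: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Backpropagate dL/d(output); return (dL/dinput, dL/dW, dL/db)."""
        gW: list[np.ndarray] = [np.empty(0)] * len(self.W)
        gb: list[np.ndarray] = [np.empty(0)] * len(self.b)
        da = dout
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            a_prev, a = cache[i], cache[i + 1]
            dz = da if i == last else da * self._act_grad(a)
            gW[i] = a_prev.T @ dz
            gb[i] = dz.sum(axis=0)
            da = dz @ self.W[i].T
        return da, gW, gb

    def sgd_step(self, gW: list[np.ndarray], gb: list[np.ndarray], lr: float) -> None:
        for i in range(len(self.W)):
            self.W[i] -= lr * gW[i]
            self.b[i] -= lr * gb[i]

    # -- (de)serialization --------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            state[f"W{i}"] = W
            state[f"b{i}"] = b
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            if state[f"W{i}"].shape != self.W[i].shape:
                raise ShapeError("decoder state shape mismatch")
            self.W[i] = np.asarray(state[f"W{i}"], dtype=float)
            self.b[i] = np.asarray(state[f"b{i}"], dtype=float)
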