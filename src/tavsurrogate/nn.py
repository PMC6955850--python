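"""Minimal dense-network engine (forward, backprop, Adamax) on numpy.

Only what the surrogate architectures need: fully-connected layers with
Softplus or linear activation, an L2 row-normalization layer for the field
code, Glorot-uniform initialization, MSE loss and the Adamax optimizer with
its standard defaults (lr=0.002, beta1=0.9, beta2=0.999, eps=1e-7).  Everything
is seeded and single-threaded-deterministic.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy.special import expit

from .exceptions import TrainingDivergenceError


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class Dense:
    """y = act(x @ W + b) with act in {linear, softplus}."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear", rng=None):
        if activation not in ("linear", "softplus"):
            raise ValueError(f"unsupported activation {activation!r}")
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._x = None
        self._z = None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.W + self.b
        if self.activation == "softplus":
            return softplus(self._z)
        return self._z

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gz = gy * expit(self._z) if self.activation == "softplus" else gy
        self.gW = self._x.T @ gz
        self.gb = gz.sum(axis=0)
        return gz @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class L2Normalize:
    """Row-wise scaling to unit Euclidean length (the code 'Normalization' layer)."""

    eps = 1e-12

    def __init__(self):
        self._y = None
        self._n = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._n = np.maximum(np.linalg.norm(x, axis=1, keepdims=True), self.eps)
        self._y = x / self._n
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        dot = np.sum(gy * self._y, axis=1, keepdims=True)
        return (gy - self._y * dot) / self._n

    def params(self):
        return []

    def grads(self):
        return []


class Standardize:
    """Fixed affine layer (x - mean) / sd; the batch-statistics alternative
    to L2 code normalization.  Statistics are set once from training codes."""

    def __init__(self, dim: int):
        self.mean = np.zeros(dim)
        self.sd = np.ones(dim)

    def set_stats(self, codes: np.ndarray) -> None:
        self.mean = codes.mean(axis=0)
        sd = codes.std(axis=0)
        self.sd = np.where(sd > 1e-12, sd, 1.0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy / self.sd

    def params(self):
        return []

    def grads(self):
        return []


class MLP:
    """A plain stack of layers with joint forward/backward passes."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, stop: int | None = None) -> np.ndarray:
        for layer in self.layers[:stop]:
            x = layer.forward(x)
        return x

    def forward_from(self, x: np.ndarray, start: int) -> np.ndarray:
        for layer in self.layers[start:]:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def copy(self) -> "MLP":
        return copy.deepcopy(self)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adamax:
    """Adamax: Adam with the infinity norm; defaults follow the original
    recommendation (also the classic Keras defaults)."""

    def __init__(self, lr: float = 0.002, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = None
        self._u = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._u = [np.zeros_like(p) for p in params]
        self.t += 1
        correction = 1.0 - self.beta1**self.t
        for p, g, m, u in zip(params, grads, self._m, self._u, strict=True):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= (self.lr / correction) * m / (u + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def fit(
    model: MLP,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    epochs: int,
    batch_size: int | None = 32,
    seed: int = 0,
    optimizer: Adamax | None = None,
    lr_decay: float = 1.0,
) -> list[float]:
    """Mini-batch MSE training; returns the per-epoch mean batch loss history.

    ``batch_size=None`` trains full-batch.  Shuffling, initialization and the
    optimizer state are all deterministic for a fixed seed.  ``lr_decay`` < 1
    multiplies the learning rate once, at 80% of the epochs, for a cheap
    final-refinement stage.
    """
    n = X.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    opt = optimizer or Adamax()
    rng = np.random.default_rng(seed)
    decay_epoch = int(0.8 * epochs) if lr_decay != 1.0 else None
    history: list[float] = []
    for epoch in range(epochs):
        if decay_epoch is not None and epoch == decay_epoch:
            opt.lr *= lr_decay
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            xb, yb = X[idx], Y[idx]
            with np.errstate(over="ignore", invalid="ignore"):
                pred = model.forward(xb)
                diff = pred - yb
                loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at optimizer step {opt.t + 1}"
                )
            model.backward(2.0 * diff / diff.size)
            opt.step(model.params(), model.grads())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
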