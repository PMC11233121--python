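"""Minimal dense-network building blocks with explicit backprop.

The three trainable models in this package (graph VAE, point autoencoder,
fusion autoencoder) are small dense architectures with custom losses, so the
forward and backward passes are written out directly in NumPy.  Everything
here is deterministic given the seed used for initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "BatchNorm", "Adam", "glorot", "relu", "drelu", "sigmoid"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def relu(x):
    return np.maximum(x, 0.0)


def drelu(x):
    return (x > 0.0).astype(float)


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine layer y = x W + b with cached input for the backward pass."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True):
        self.W = glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ gy
        if self.b is not None:
            self.gb += gy.sum(axis=0)
        return gy @ self.W.T

    def params(self):
        if self.b is None:
            return [(self.W, self.gW)]
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW[...] = 0.0
        if self.gb is not None:
            self.gb[...] = 0.0


class BatchNorm:
    """Batch normalization over axis 0, with running statistics for eval.

    Batch statistics are undefined for a single sample, so a batch of one
    row passes through un-normalized (affine transform only) and leaves the
    running statistics untouched; evaluation always uses running statistics.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            normalize = True
        elif self.training:  # single-sample batch: affine pass-through
            mean, var, normalize = None, None, False
        else:
            mean, var, normalize = self.run_mean, self.run_var, True
        if normalize:
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
        else:
            inv = np.ones(x.shape[1])
            xhat = x
        self._cache = (xhat, inv, normalize and self.training)
        return self.gamma * xhat + self.beta

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, batch_stats = self._cache
        m = gy.shape[0]
        self.ggamma += (gy * xhat).sum(axis=0)
        self.gbeta += gy.sum(axis=0)
        gxhat = gy * self.gamma
        if not batch_stats:  # pass-through or frozen statistics
            return gxhat * inv
        # standard batchnorm backward (training-mode statistics)
        return (inv / m) * (
            m * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def zero_grad(self):
        self.ggamma[...] = 0.0
        self.gbeta[...] = 0.0


class Adam:
    """Adam over a fixed list of (param, grad) array pairs, updated in place."""

    def __init__(self, param_grads, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pg = list(param_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pg):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
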