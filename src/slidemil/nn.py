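"""Minimal dense-network building blocks with explicit gradients.

The MIL model is small (a few dense layers around a softmax-weighted
pooling step), so layers carry their own gradient buffers and the model
classes wire the chain rule by hand. All arrays are float64 row-major,
inputs shaped (n_samples, n_features).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Tanh", "ReLU", "Sequential", "Adam", "softmax", "log_softmax"]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Dense:
    """Affine layer y = x W + b with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)

    params_and_grads = ()
    n_params = 0


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    params_and_grads = ()
    n_params = 0


class Sequential:
    """Plain layer stack; forward caches whatever backward needs."""

    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads)
        return out

    @property
    def n_params(self):
        return sum(layer.n_params for layer in self.layers)


class Adam:
    """Adaptive moment estimation with the customary defaults.

    Only the initial learning rate is exposed by the training protocol;
    beta/epsilon stay at the method's standard values.
    """

    def __init__(self, params_and_grads, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = list(params_and_grads)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.slots]
        self.v = [np.zeros_like(p) for p, _ in self.slots]
        self.t = 0

    def zero_grad(self):
        for _, g in self.slots:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.slots):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
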