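"""Minimal dense neural-network layers with explicit backpropagation.

Everything operates on (batch, features) float64 arrays. Each layer exposes
``forward``/``backward``; parameters and their gradients are flat lists so a
single Adam instance can update a whole model. Deterministic given the
initializing Generator.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Tanh:
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._y is not None
        return g * (1.0 - self._y**2)

    params: list = []
    grads: list = []


class ResidualBlock:
    """y = x + dense2(tanh(dense1(x))) — identity-mapping residual unit."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.d1 = Dense(width, width, rng)
        self.act = Tanh()
        self.d2 = Dense(width, width, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.d2.forward(self.act.forward(self.d1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g + self.d1.backward(self.act.backward(self.d2.backward(g)))

    @property
    def params(self):
        return self.d1.params + self.d2.params

    @property
    def grads(self):
        return self.d1.grads + self.d2.grads


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [p for layer in self.layers for p in layer.grads]


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
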