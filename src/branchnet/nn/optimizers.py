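"""The three supported optimizers.

SGD is preset with Nesterov momentum 0.9; RMSprop and Adam run at their
standard published defaults apart from the user-chosen learning rate.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, learning_rate: float):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.learning_rate = learning_rate

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    """Stochastic gradient descent with Nesterov momentum fixed at 0.9."""

    momentum = 0.9
    nesterov = True

    def __init__(self, learning_rate: float):
        super().__init__(learning_rate)
        self._velocity: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._velocity is None:
            self._velocity = [np.zeros_like(p) for p in params]
        lr = self.learning_rate
        for p, g, v in zip(params, grads, self._velocity):
            v *= self.momentum
            v -= lr * g
            p += self.momentum * v - lr * g


class RMSprop(Optimizer):
    rho = 0.9
    eps = 1e-7

    def __init__(self, learning_rate: float):
        super().__init__(learning_rate)
        self._sq: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._sq is None:
            self._sq = [np.zeros_like(p) for p in params]
        for p, g, a in zip(params, grads, self._sq):
            a *= self.rho
            a += (1 - self.rho) * g * g
            p -= self.learning_rate * g / (np.sqrt(a) + self.eps)


class Adam(Optimizer):
    beta1 = 0.9
    beta2 = 0.999
    eps = 1e-7

    def __init__(self, learning_rate: float):
        super().__init__(learning_rate)
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        lr = self.learning_rate * np.sqrt(1 - b2 ** self._t) / (1 - b1 ** self._t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * m / (np.sqrt(v) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str, learning_rate: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer '{name}'; choose from {sorted(_OPTIMIZERS)}") from None
    return cls(learning_rate)
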