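"""Parameters, initialisation and the Adam optimiser."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from ._tensor import Tensor


class Parameter(Tensor):
    """A leaf tensor that receives gradients and is updated by the optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Parameter:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Parameter(rng.uniform(-limit, limit, size=shape))


def normal(rng: np.random.Generator, shape: tuple[int, ...], scale: float = 0.02) -> Parameter:
    return Parameter(rng.normal(0.0, scale, size=shape))


def zeros(shape: tuple[int, ...] | int) -> Parameter:
    return Parameter(np.zeros(shape))


def ones(shape: tuple[int, ...] | int) -> Parameter:
    return Parameter(np.ones(shape))


def identity(n: int) -> Parameter:
    return Parameter(np.eye(n))


def zero_grads(params: Iterable[Parameter]) -> None:
    for p in params:
        p.grad = None


def clip_global_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm (useful for logging).
    """
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad = p.grad * scale
    return total


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
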