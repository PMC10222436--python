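"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the extraction model is built on: a ``Tensor``
wraps an ``ndarray`` and records the operations applied to it so that
``backward()`` can accumulate gradients into every parameter that
contributed to a scalar objective.  Only the operations the cascade model
needs are provided (broadcasting arithmetic, matmul, reductions, reshaping,
gather-style indexing, softmax, sigmoid, tanh, log/exp, clip).

Gradients use the standard conventions: broadcasting in the forward pass is
undone by summation in the backward pass, and integer-array indexing
scatters with ``np.add.at`` so repeated indices accumulate.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out = Tensor._node(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._node(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.data.shape),
                       _unbroadcast(g * a.data, b.data.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._node(
            a.data / b.data, (a, b),
            lambda g: (_unbroadcast(g / b.data, a.data.shape),
                       _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        return Tensor._node(
            a.data ** e, (a,),
            lambda g: (g * e * a.data ** (e - 1.0),),
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
            return ga, gb

        return Tensor._node(out_data, (a, b), backward)

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._node(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(a.data.shape),))

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor._node(a.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._node(np.swapaxes(a.data, ax1, ax2), (a,),
                            lambda g: (np.swapaxes(g, ax1, ax2),))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._node(a.data[idx], (a,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- elementwise functions ---------------------------------------------------

def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return Tensor._node(out_data, (x,), lambda g: (g * out_data,))


def log(x: Tensor) -> Tensor:
    return Tensor._node(np.log(x.data), (x,), lambda g: (g / x.data,))


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)
    return Tensor._node(out_data, (x,), lambda g: (g * (1.0 - out_data ** 2),))


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return Tensor._node(out_data, (x,), lambda g: (g * out_data * (1.0 - out_data),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._node(x.data * mask, (x,), lambda g: (g * mask,))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    c = np.sqrt(2.0 / np.pi)
    inner = c * (x + 0.044715 * x * x * x)
    return 0.5 * x * (1.0 + tanh(inner))


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes through only inside the window."""
    mask = (x.data >= lo) & (x.data <= hi)
    return Tensor._node(np.clip(x.data, lo, hi), (x,), lambda g: (g * mask,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor._node(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)
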