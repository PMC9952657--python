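"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in this package is small enough that a compact
tape-based engine on top of :mod:`numpy` covers everything it needs:
broadcast arithmetic, batched matrix products, shape manipulation,
softmax/GELU nonlinearities and strided slicing (from which the strided
convolutions are composed).  Gradients are accumulated into ``.grad`` on
leaf tensors created with ``requires_grad=True``.

All data is kept in float64; the models here are tiny and the test-suite
oracles compare at tight tolerances.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import special

__all__ = ["Tensor", "concatenate", "softmax", "gelu"]

_DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = _as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data + o.data, req, (self, o))
        if req:
            def back(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(g, o.shape))
            out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        o = _as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data * o.data, req, (self, o))
        if req:
            def back(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * o.data, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(g * self.data, o.shape))
            out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data / o.data, req, (self, o))
        if req:
            def back(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / o.data, self.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))
            out._backward = back
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        o = _as_tensor(other)
        req = self.requires_grad or o.requires_grad
        out = Tensor(self.data @ o.data, req, (self, o))
        if req:
            a, b = self.data, o.data

            def back(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                if o.requires_grad:
                    o._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))
            out._backward = back
        return out

    def __rmatmul__(self, other):
        return _as_tensor(other) @ self

    # ------------------------------------------------------------- elementwise
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if out.requires_grad:
            shape = self.shape

            def back(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape).copy() if np.ndim(g) else np.full(shape, g))
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accumulate(np.broadcast_to(gg, shape).copy())
            out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            orig = self.shape
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = tuple(np.argsort(axes))
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))
        if out.requires_grad:
            shape = self.shape

            def back(g):
                z = np.zeros(shape, dtype=_DTYPE)
                z[key] += g
                self._accumulate(z)
            out._backward = back
        return out

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        out = Tensor(np.pad(self.data, pad_width), self.requires_grad, (self,))
        if out.requires_grad:
            sl = tuple(slice(b, b + s) for (b, _), s in zip(pad_width, self.shape))
            out._backward = lambda g: self._accumulate(g[sl])
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))
        out._backward = back
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = _as_tensor(x)
    cdf = 0.5 * (1.0 + special.erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, x.requires_grad, (x,))
    if out.requires_grad:
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data ** 2)
        out._backward = lambda g: x._accumulate(g * (cdf + x.data * pdf))
    return out
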