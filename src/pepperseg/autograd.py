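"""Reverse-mode automatic differentiation on NumPy arrays.

The co-design method treats a physical optical filter as the first layer of a
neural network and back-propagates a segmentation loss through the whole image
formation chain.  This module provides the tape: a :class:`Tensor` wraps a
float64 ``ndarray``, records the ops applied to it, and :meth:`Tensor.backward`
walks the graph in reverse topological order accumulating gradients.

Everything is float64.  That is deliberate: the physical-constraint and
gradient-correctness checks compare analytic gradients against central finite
differences, and double precision keeps the comparison meaningful.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "channel_project", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph."""

    # Make NumPy defer binary ops (ndarray @ Tensor etc.) to our reflected ops.
    __array_ufunc__ = None

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward_fn = None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- graph ops
    @staticmethod
    def _result(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        if any(isinstance(p, Tensor) and p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward_fn = backward_fn
        return out

    @staticmethod
    def _acc(t, g) -> None:
        if isinstance(t, Tensor) and t.requires_grad:
            g = _unbroadcast(np.asarray(g), t.data.shape)
            t.grad = g if t.grad is None else t.grad + g

    def backward(self, grad=None) -> None:
        """Back-propagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep U-Nets overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        od = other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)

        def bwd(g):
            Tensor._acc(self, g)
            Tensor._acc(other, g)

        return Tensor._result(self.data + od, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        od = other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)
        sd = self.data

        def bwd(g):
            Tensor._acc(self, g * od)
            Tensor._acc(other, g * sd)

        return Tensor._result(sd * od, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g):
            Tensor._acc(self, -g)

        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        od = other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)

        def bwd(g):
            Tensor._acc(self, g)
            Tensor._acc(other, -g)

        return Tensor._result(self.data - od, (self, other), bwd)

    def __rsub__(self, other):
        od = np.asarray(other, dtype=np.float64)

        def bwd(g):
            Tensor._acc(self, -g)

        return Tensor._result(od - self.data, (self,), bwd)

    def __truediv__(self, other):
        od = other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)
        sd = self.data
        out = sd / od

        def bwd(g):
            Tensor._acc(self, g / od)
            Tensor._acc(other, -g * sd / (od * od))

        return Tensor._result(out, (self, other), bwd)

    def __rtruediv__(self, other):
        od = np.asarray(other, dtype=np.float64)
        sd = self.data

        def bwd(g):
            Tensor._acc(self, -g * od / (sd * sd))

        return Tensor._result(od / sd, (self,), bwd)

    def __pow__(self, exponent: float):
        e = float(exponent)
        sd = self.data

        def bwd(g):
            Tensor._acc(self, g * e * sd ** (e - 1.0))

        return Tensor._result(sd ** e, (self,), bwd)

    def __matmul__(self, other):
        od = other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)
        sd = self.data

        def bwd(g):
            g = np.asarray(g)
            if sd.ndim == 2 and od.ndim == 1:
                Tensor._acc(self, np.outer(g, od))
                Tensor._acc(other, sd.T @ g)
            elif sd.ndim == 1 and od.ndim == 2:
                Tensor._acc(self, g @ od.T)
                Tensor._acc(other, np.outer(sd, g))
            elif sd.ndim == 1 and od.ndim == 1:
                Tensor._acc(self, g * od)
                Tensor._acc(other, g * sd)
            else:
                Tensor._acc(self, g @ np.swapaxes(od, -1, -2))
                Tensor._acc(other, np.swapaxes(sd, -1, -2) @ g)

        return Tensor._result(sd @ od, (self, other), bwd)

    def __rmatmul__(self, other):
        od = np.asarray(other, dtype=np.float64)
        sd = self.data

        def bwd(g):
            g = np.asarray(g)
            if od.ndim == 2 and sd.ndim == 1:
                Tensor._acc(self, od.T @ g)
            elif od.ndim == 1 and sd.ndim == 2:
                Tensor._acc(self, np.outer(od, g))
            else:
                Tensor._acc(self, np.swapaxes(od, -1, -2) @ g)

        return Tensor._result(od @ sd, (self,), bwd)

    # ----------------------------------------------------------- elementwise
    def log(self):
        sd = self.data

        def bwd(g):
            Tensor._acc(self, g / sd)

        return Tensor._result(np.log(sd), (self,), bwd)

    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            Tensor._acc(self, g * out)

        return Tensor._result(out, (self,), bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            Tensor._acc(self, g * out * (1.0 - out))

        return Tensor._result(out, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            Tensor._acc(self, g * mask)

        return Tensor._result(self.data * mask, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp to [lo, hi]; gradient passes where the input is in range."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            Tensor._acc(self, g * mask)

        return Tensor._result(np.clip(self.data, lo, hi), (self,), bwd)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def bwd(g):
            Tensor._acc(self, g * mask)

        return Tensor._result(np.maximum(self.data, lo), (self,), bwd)

    def clamp_max(self, hi: float):
        mask = self.data <= hi

        def bwd(g):
            Tensor._acc(self, g * mask)

        return Tensor._result(np.minimum(self.data, hi), (self,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._acc(self, np.broadcast_to(g, shape))

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            Tensor._acc(self, np.asarray(g).reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), bwd)

    def __getitem__(self, idx):
        shape = self.data.shape

        def bwd(g):
            full = np.zeros(shape, dtype=np.float64)
            full[idx] = g
            Tensor._acc(self, full)

        return Tensor._result(self.data[idx], (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis``; the backward pass splits the gradient."""
    tensors = list(tensors)
    datas = [t.data if isinstance(t, Tensor) else np.asarray(t, dtype=np.float64) for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._acc(t, g[tuple(sl)])

    return Tensor._result(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def channel_project(x: Tensor, matrix: np.ndarray) -> Tensor:
    """Project the channel axis of a (B, N, H, W) tensor with a (K, N) matrix.

    This is the 1x1 convolution form of a camera-spectral-response layer:
    out[b, k, h, w] = sum_n matrix[k, n] * x[b, n, h, w].
    """
    x = as_tensor(x)
    m = np.asarray(matrix, dtype=np.float64)
    out = np.einsum("kn,bnhw->bkhw", m, x.data, optimize=True)

    def bwd(g):
        Tensor._acc(x, np.einsum("kn,bkhw->bnhw", m, np.asarray(g), optimize=True))

    return Tensor._result(out, (x,), bwd)
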