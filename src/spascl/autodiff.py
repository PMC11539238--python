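"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The training objective is a composition of dense matrix products,
PReLU/sigmoid nonlinearities and log terms on a full graph, so a small
tape-based engine is all that is needed: no broadcasting beyond
scalar/row/column cases, no in-place mutation, float64 throughout.
Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "matmul", "prelu", "sigmoid", "log", "clip"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: (g.T,)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    pg = _unbroadcast(pg, parent.data.shape)
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)
            out._backward = lambda g: (g, g)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)
            out._backward = lambda g: (g * other.data, g * self.data)
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    return (np.broadcast_to(g, shape).copy(),)
                gg = g if keepdims else np.expand_dims(g, axis)
                return (np.broadcast_to(gg, shape).copy(),)

            out._parents = (self,)
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def square(self) -> "Tensor":
        return self * self

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: (g.reshape(old),)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad)
    if out.requires_grad:
        out._parents = (a, b)
        out._backward = lambda g: (g @ b.data.T, a.data.T @ g)
    return out


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a learnable scalar negative slope: max(x,0) + slope*min(x,0)."""
    x, slope = as_tensor(x), as_tensor(slope)
    neg = np.minimum(x.data, 0.0)
    out = Tensor(np.maximum(x.data, 0.0) + slope.data * neg,
                 x.requires_grad or slope.requires_grad)
    if out.requires_grad:
        mask = (x.data >= 0.0).astype(np.float64)

        def bw(g):
            gx = g * (mask + slope.data * (1.0 - mask))
            gs = np.sum(g * neg)
            return gx, np.asarray(gs)

        out._parents = (x, slope)
        out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(s, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: (g * s * (1.0 - s),)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: (g / x.data,)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi] (straight-through inside)."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), x.requires_grad)
    if out.requires_grad:
        inside = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
        out._parents = (x,)
        out._backward = lambda g: (g * inside,)
    return out
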