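"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the 1-D residual shrinkage network needs:
broadcast arithmetic, matmul, 1-D convolution (im2col), ReLU, sigmoid,
axis reductions, absolute value, sqrt, and the soft-threshold shrinkage
operator with its piecewise-constant subgradient (1 outside the dead zone,
0 inside).  Float64 throughout; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "soft_threshold_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self._needs(other))
        if out.requires_grad:
            out._prev = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self._needs(other))
        if out.requires_grad:
            out._prev = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, self._needs(other))
        if out.requires_grad:
            out._prev = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.data.shape))
            out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self._needs(other))
        if out.requires_grad:
            out._prev = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape / reductions ------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)

            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * 0.5 / r)
        return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x (N,Cin,L), w (Cout,Cin,K), b (Cout,)."""
    N, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lout = (L + 2 * pad - K) // stride + 1
    idx = stride * np.arange(Lout)[:, None] + np.arange(K)[None, :]
    cols = xp[:, :, idx]                               # (N, Cin, Lout, K)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(N * Lout, Cin * K)
    W2 = w.data.reshape(Cout, Cin * K)
    out_data = (cols2 @ W2.T + b.data).reshape(N, Lout, Cout).transpose(0, 2, 1)
    out = Tensor(out_data, x.requires_grad or w.requires_grad or b.requires_grad)
    if out.requires_grad:
        out._prev = (x, w, b)

        def bwd(g):
            g2 = g.transpose(0, 2, 1).reshape(N * Lout, Cout)
            if w.requires_grad:
                w._accum((g2.T @ cols2).reshape(Cout, Cin, K))
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ W2).reshape(N, Lout, Cin, K).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                np.add.at(gxp, (slice(None), slice(None), idx), gcols)
                x._accum(gxp[:, :, pad:pad + L] if pad else gxp)
        out._backward = bwd
    return out


def soft_threshold_op(x: Tensor, tau: Tensor) -> Tensor:
    """Shrinkage y = sign(x) * max(|x| - tau, 0), tau broadcastable to x.

    The subgradient w.r.t. x is 1 where |x| > tau and 0 inside the dead zone;
    w.r.t. tau it is -sign(x) where the unit is active.
    """
    active = np.abs(x.data) > tau.data
    sgn = np.sign(x.data)
    y = sgn * np.maximum(np.abs(x.data) - tau.data, 0.0)
    out = Tensor(y, x.requires_grad or tau.requires_grad)
    if out.requires_grad:
        out._prev = (x, tau)

        def bwd(g):
            if x.requires_grad:
                x._accum(g * active)
            if tau.requires_grad:
                tau._accum(_unbroadcast(-g * sgn * active, tau.data.shape))
        out._backward = bwd
    return out
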