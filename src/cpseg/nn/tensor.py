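"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the segmentation networks and Dice losses
need: broadcast arithmetic, reductions, relu/sigmoid, 3x3/1x1 convolution,
2x2 average pooling, nearest-neighbour upsampling and channel concatenation.
Gradients accumulate into ``Tensor.grad`` after ``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ---- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return self._make(self.data ** e, (self,), backward)

    # ---- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).astype(DTYPE))
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).astype(DTYPE))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    # ---- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    # ---- backward pass ---------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros(self.shape, dtype=DTYPE)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones(self.shape, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


# ---- spatial primitives (B, C, H, W) ------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 cross-correlation; ``w`` is (out, in, k, k), k odd."""
    k = w.shape[2]
    p = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    out = np.einsum("bchwij,ocij->bohw", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data[:, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, cols=cols, k=k, p=p):
        if w.requires_grad:
            w._accum(np.einsum("bchwij,bohw->ocij", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
            gcols = sliding_window_view(gp, (k, k), axis=(2, 3))
            wflip = w.data[:, :, ::-1, ::-1]
            x._accum(np.einsum("bohwij,ocij->bchw", gcols, wflip, optimize=True))

    return x._make(out, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling; spatial dims must be even."""
    B, C, H, W = x.shape
    out = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g, x=x):
        if x.requires_grad:
            x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    return x._make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g, x=x):
        B, C, H, W = x.shape
        if x.requires_grad:
            x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return x._make(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, tensors=tensors, splits=splits, axis=axis):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out
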