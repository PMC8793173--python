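"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a small, self-contained autodiff core providing exactly the
operations the segmentation networks need: elementwise arithmetic,
reductions, stride-1 same-padding N-D convolution, factor-based max
pooling, linear-interpolation upsampling, concatenation and the usual
activations.  Gradients are accumulated by topological traversal of the
operation graph.  All tensors are float32; statistics that need wider
accumulation (e.g. FRN's mean of squares) widen internally.
"""
from __future__ import annotations

import contextlib
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    track = grad_enabled() and any(
        p.requires_grad or p._parents for p in parents
    )
    if track:
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1))

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / np.maximum(out_data, 1e-30))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _node(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        a._accumulate(g * mask)

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out_data[~pos] = ez / (1.0 + ez)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _node(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    """Elementwise max with broadcasting; ties split the gradient evenly."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)

    def backward(g):
        ga = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * ga, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * (1.0 - ga), b.shape))

    return _node(out_data, (a, b), backward)


# -- reductions / shape ------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float64)
    out_data = out_data.astype(np.float32)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g2, a.shape))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _node(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(ts), backward)


# -- convolution -------------------------------------------------------------

def _conv_data(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' N-D cross-correlation; x (N,C,*S), w (Co,Ci,*k)."""
    d = x.ndim - 2
    k = w.shape[2:]
    pads = [(0, 0), (0, 0)] + [((kk - 1) // 2, (kk - 1) // 2) for kk in k]
    xp = np.pad(x, pads) if any(kk > 1 for kk in k) else x
    win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + d)))
    axes_x = (1,) + tuple(range(2 + d, 2 + 2 * d))
    axes_w = (1,) + tuple(range(2, 2 + d))
    out = np.tensordot(win, w, axes=(axes_x, axes_w))
    return np.ascontiguousarray(np.moveaxis(out, -1, 1))


def _conv_dw(x: np.ndarray, go: np.ndarray, kshape) -> np.ndarray:
    d = x.ndim - 2
    pads = [(0, 0), (0, 0)] + [((kk - 1) // 2, (kk - 1) // 2) for kk in kshape]
    xp = np.pad(x, pads) if any(kk > 1 for kk in kshape) else x
    win = sliding_window_view(xp, kshape, axis=tuple(range(2, 2 + d)))
    red = (0,) + tuple(range(2, 2 + d))
    # dW[co, ci, *k] = sum_{n, *s} go[n, co, *s] * win[n, ci, *s, *k]
    dw = np.tensordot(go, win, axes=(red, red))
    return dw


def conv_nd(x, w) -> Tensor:
    """Same-padding stride-1 convolution (cross-correlation), rank 2 or 3.

    All kernel sizes must be odd.  Bias, when wanted, is a separate add.
    """
    x, w = as_tensor(x), as_tensor(w)
    if x.shape[1] != w.shape[1]:
        raise DimensionError(
            f"conv channel mismatch: input has {x.shape[1]}, kernel expects {w.shape[1]}"
        )
    out_data = _conv_data(x.data, w.data)

    def backward(g):
        if w.requires_grad or w._parents:
            w._accumulate(_conv_dw(x.data, g, w.shape[2:]))
        if x.requires_grad or x._parents:
            d = x.data.ndim - 2
            w_swap = np.flip(w.data, axis=tuple(range(2, 2 + d))).swapaxes(0, 1)
            x._accumulate(_conv_data(g, np.ascontiguousarray(w_swap)))

    return _node(out_data, (x, w), backward)


# -- pooling / resampling ----------------------------------------------------

def max_pool(x, factor: int) -> Tensor:
    """Max pooling with an integer factor along every spatial axis."""
    x = as_tensor(x)
    d = x.ndim - 2
    for ax in range(2, 2 + d):
        if x.shape[ax] % factor:
            raise DimensionError(
                f"spatial axis {ax - 2} of size {x.shape[ax]} not divisible by pool factor {factor}"
            )
    newshape = list(x.shape[:2])
    pool_axes = []
    for ax in range(2, 2 + d):
        newshape += [x.shape[ax] // factor, factor]
        pool_axes.append(len(newshape) - 1)
    xr = x.data.reshape(newshape)
    out_data = xr.max(axis=tuple(pool_axes))

    def backward(g):
        out_kept = np.expand_dims(out_data, tuple(pool_axes))
        mask = (xr == out_kept).astype(np.float32)
        counts = mask.sum(axis=tuple(pool_axes), keepdims=True)
        g_kept = np.expand_dims(g, tuple(pool_axes))
        gx = mask / counts * g_kept
        x._accumulate(gx.reshape(x.shape))

    return _node(out_data, (x,), backward)


@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """1-D linear interpolation matrix (out=n_in*factor, in=n_in).

    Uses the half-pixel (align_corners=False) source mapping with edge
    clamping, the convention of mainstream frameworks.
    """
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    i0 = np.floor(src).astype(int)
    t = (src - i0).astype(np.float64)
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in), dtype=np.float64)
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0c), 1.0 - t)
    np.add.at(m, (rows, i1c), t)
    return m.astype(np.float32)


def _apply_axis_matrix(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    out = np.tensordot(x, m, axes=([axis], [1]))
    return np.ascontiguousarray(np.moveaxis(out, -1, axis))


def upsample_linear(x, factor: int) -> Tensor:
    """Bi/tri-linear upsampling by an integer factor on all spatial axes."""
    x = as_tensor(x)
    d = x.ndim - 2
    data = x.data
    mats = []
    for ax in range(2, 2 + d):
        m = _interp_matrix(data.shape[ax], factor)
        data = _apply_axis_matrix(data, m, ax)
        mats.append(m)

    def backward(g):
        gx = g
        for ax, m in zip(range(2, 2 + d), mats):
            gx = _apply_axis_matrix(gx, m.T, ax)
        x._accumulate(gx)

    return _node(data, (x,), backward)


class DimensionError(ValueError):
    """Shape or channel-count mismatch."""
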