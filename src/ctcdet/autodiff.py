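"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized for the detector in this package: dense and
convolutional primitives with analytic backward passes, accumulated onto a
dynamically built graph and released after :meth:`Tensor.backward`.  Gradients
are plain numpy arrays stored on ``Tensor.grad``; intermediate tensors retain
their gradients too, which is what class-activation mapping needs.

Only the operations the detector uses are provided.  All convolution lowering
goes through im2col/col2im so the heavy lifting is a single GEMM per layer.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add", "sub", "mul", "div", "neg", "pow_scalar",
    "matmul", "reshape", "transpose", "concat",
    "tsum", "tmean", "amax",
    "relu", "sigmoid", "exp", "log", "log_softmax",
    "take", "take2d", "smooth_l1",
    "conv2d", "conv_transpose2d", "maxpool2d",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph ---------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None):
        """Backpropagate from this tensor; seeds with ones if not given."""
        if seed is None:
            seed = np.ones_like(self.data)
        _accum(self, np.asarray(seed, dtype=self.data.dtype))
        # iterative topological order (graphs can be a few hundred nodes deep)
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
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise & reductions
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(out_data, (a, b), bwd)


def neg(a: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            _accum(a, -g)

    return _make(-a.data, (a,), bwd)


def pow_scalar(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), bwd)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape).astype(a.dtype, copy=True))
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.ndim for ax in axes):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.shape).astype(a.dtype, copy=True))

    return _make(out_data, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def amax(a: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    """Max along one axis; gradient flows to the (first) argmax only."""
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def bwd(g):
        if not a.requires_grad:
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        buf = np.zeros_like(a.data)
        np.put_along_axis(buf, np.expand_dims(idx, axis), gg, axis=axis)
        _accum(a, buf)

    return _make(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * mask)

    return _make(out_data, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def bwd(g):
        if a.requires_grad:
            sm = np.exp(out_data)
            _accum(a, g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), bwd)


def smooth_l1(a: Tensor) -> Tensor:
    """Elementwise Huber-style loss: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    absx = np.abs(a.data)
    out_data = np.where(absx < 1.0, 0.5 * a.data * a.data, absx - 0.5)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * np.clip(a.data, -1.0, 1.0))

    return _make(out_data.astype(a.dtype), (a,), bwd)


# ---------------------------------------------------------------------------
# shape manipulation / indexing
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def bwd(g):
        if a.requires_grad:
            _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                _accum(t, gp)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def take(a: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    indices = np.asarray(indices)

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, (slice(None),) * axis + (indices,), g)
            _accum(a, buf)

    return _make(np.take(a.data, indices, axis=axis), (a,), bwd)


def take2d(a: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Fancy-index a 2-D tensor at (rows[i], cols[i]); returns a 1-D tensor."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, (rows, cols), g)
            _accum(a, buf)

    return _make(a.data[rows, cols], (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, g @ b.data.T)
        if b.requires_grad:
            _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), bwd)


# ---------------------------------------------------------------------------
# convolution lowering
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Lower to columns of layout (N, C*kh*kw, Hp*Wp) using contiguous slice copies."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    hp = (h - kh) // stride + 1
    wp = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, hp, wp), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * hp:stride, j:j + stride * wp:stride]
    return cols.reshape(n, c * kh * kw, hp * wp), hp, wp


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, hp, wp) -> np.ndarray:
    """Adjoint of :func:`_im2col`; dcols has layout (N, C*kh*kw, Hp*Wp)."""
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, kh, kw, hp, wp)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * hp:stride, j:j + stride * wp:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


def _conv_fwd(x, w, stride, pad):
    o, c, kh, kw = w.shape
    cols, hp, wp = _im2col(x, kh, kw, stride, pad)
    out = np.matmul(w.reshape(o, -1)[None], cols)       # (N, O, Hp*Wp)
    return out.reshape(x.shape[0], o, hp, wp), cols, hp, wp


def _conv_bwd_data(dout, w, stride, pad, in_hw):
    o, c, kh, kw = w.shape
    n = dout.shape[0]
    hp, wp = dout.shape[2], dout.shape[3]
    dcols = np.matmul(w.reshape(o, -1).T[None], dout.reshape(n, o, hp * wp))
    return _col2im(dcols, (n, c, *in_hw), kh, kw, stride, pad, hp, wp)


def _conv_bwd_weight(cols, dout, wshape):
    o = wshape[0]
    n = dout.shape[0]
    dm = dout.reshape(n, o, -1)
    return np.matmul(dm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wshape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation; ``w`` is (out_ch, in_ch, kh, kw)."""
    out_data, cols, hp, wp = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    in_hw = x.shape[2:]

    def bwd(g):
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            _accum(w, _conv_bwd_weight(cols, g, w.shape))
        if x.requires_grad:
            _accum(x, _conv_bwd_data(g, w.data, stride, pad, in_hw))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Transpose convolution (adjoint of conv2d); ``w`` is (in_ch, out_ch, kh, kw).

    Output spatial size is ``stride * (in - 1) + k - 2 * pad``.
    """
    cin, cout, kh, kw = w.shape
    n, _, h, wd = x.shape
    ho = stride * (h - 1) + kh - 2 * pad
    wo = stride * (wd - 1) + kw - 2 * pad
    out_data = _conv_bwd_data(x.data, w.data, stride, pad, (ho, wo))
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or w.requires_grad:
            cols, hp, wp = _im2col(g, kh, kw, stride, pad)
            if x.requires_grad:
                dx = np.matmul(w.data.reshape(cin, -1)[None], cols).reshape(n, cin, hp, wp)
                _accum(x, dx)
            if w.requires_grad:
                _accum(w, _conv_bwd_weight(cols, x.data, w.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def maxpool2d(x: Tensor, k: int = 2, ceil_mode: bool = False) -> Tensor:
    """Non-overlapping k x k max pooling (stride = k), optional ceil padding."""
    n, c, h, w = x.shape
    ph = (-h) % k if ceil_mode else 0
    pw = (-w) % k if ceil_mode else 0
    if not ceil_mode and (h % k or w % k):
        raise ValueError(f"pool input {h}x{w} not divisible by {k} (ceil_mode off)")
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    hp, wp = xp.shape[2] // k, xp.shape[3] // k
    win = xp.reshape(n, c, hp, k, wp, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp, wp, k * k)
    idx = np.argmax(win, axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        buf = np.zeros((n, c, hp, wp, k * k), dtype=g.dtype)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        buf = buf.reshape(n, c, hp, wp, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, hp * k, wp * k)
        _accum(x, buf[:, :, :h, :w])

    return _make(out_data, (x,), bwd)
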