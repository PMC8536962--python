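"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the segmentation network
needs — size-preserving convolution, stride-2 transposed convolution,
2x2 max pooling, batch normalisation, dropout, ELU/sigmoid, channel
concatenation and the elementwise/reduction arithmetic of the loss —
with float32 storage and NHWC layout throughout.  Convolutions are
evaluated as tensordot contractions over sliding-window views, so the
heavy lifting is delegated to BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose_2x2",
    "maxpool_2x2",
    "batchnorm_train",
    "dropout",
    "elu",
    "sigmoid",
    "log",
    "clip",
    "tsum",
    "tmean",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    # -- graph traversal -------------------------------------------------

    def backward(self):
        """Accumulate gradients of ``self`` (summed if non-scalar) into
        every reachable tensor with ``requires_grad``."""
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
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate gradients to bound memory
                if node is not self:
                    node.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    # -- operator sugar --------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise arithmetic ---------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a, b):
    a = as_tensor(a)
    if not isinstance(b, Tensor) and np.isscalar(b):
        s = float(b)

        def bw_s(g):
            if a.requires_grad:
                a._accum(g * s)

        return Tensor(a.data * s, parents=(a,), backward=bw_s)
    b = as_tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return Tensor(a.data * b.data, parents=(a, b), backward=bw)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * out_data / b.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def log(x):
    x = as_tensor(x)

    def bw(g):
        if x.requires_grad:
            x._accum(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=bw)


def clip(x, lo, hi):
    """Clip values to [lo, hi]; gradient passes only strictly inside."""
    x = as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(np.clip(x.data, lo, hi), parents=(x,), backward=bw)


def reshape(x, shape):
    x = as_tensor(x)
    orig = x.shape

    def bw(g):
        if x.requires_grad:
            x._accum(g.reshape(orig))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=bw)


def tsum(x, axis=None, keepdims=False):
    x = as_tensor(x)

    def bw(g):
        if not x.requires_grad:
            return
        if axis is None:
            x._accum(np.broadcast_to(g, x.shape))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            x._accum(np.broadcast_to(gg, x.shape))

    return Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,), backward=bw)


def tmean(x, axis=None, keepdims=False):
    x = as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- activations ---------------------------------------------------------


def elu(x, alpha=1.0):
    x = as_tensor(x)
    neg = x.data < 0
    out_data = np.where(neg, alpha * np.expm1(x.data), x.data).astype(np.float32)

    def bw(g):
        if x.requires_grad:
            x._accum(g * np.where(neg, out_data + alpha, 1.0))

    return Tensor(out_data, parents=(x,), backward=bw)


def sigmoid(x):
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        if x.requires_grad:
            x._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bw)


# -- structural ops ------------------------------------------------------


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


# -- convolutions (NHWC) -------------------------------------------------


def conv2d(x, w, b=None):
    """Size-preserving stride-1 correlation.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout) with odd kh, kw; b: (Cout,).
    """
    x, w = as_tensor(x), as_tensor(w)
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    else:
        xp = x.data
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,Cin,kh,kw)
    out_data = np.tensordot(win, w.data, axes=([4, 5, 3], [0, 1, 2]))
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def bw(g):
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            # (Cin,kh,kw,Cout) -> (kh,kw,Cin,Cout)
            dw = np.tensordot(win, g, axes=([0, 1, 2], [0, 1, 2]))
            w._accum(dw.transpose(1, 2, 0, 3))
        if x.requires_grad:
            wf = w.data[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,Cout,Cin)
            if ph or pw:
                gp = np.pad(g, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
            else:
                gp = g
            gwin = sliding_window_view(gp, (kh, kw), axis=(1, 2))
            x._accum(np.tensordot(gwin, wf, axes=([4, 5, 3], [0, 1, 2])))

    return Tensor(out_data, parents=tuple(parents), backward=bw)


def conv_transpose_2x2(x, w, b=None):
    """Stride-2, kernel-2 transposed convolution (learned 2x upsampling).

    x: (N, H, W, Cin); w: (2, 2, Cin, Cout); output (N, 2H, 2W, Cout).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, h, wd, cin = x.shape
    cout = w.shape[3]
    t = np.tensordot(x.data, w.data, axes=([3], [2]))  # (N,H,W,2,2,Cout)
    out_data = t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * wd, cout)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def bw(g):
        gg = g.reshape(n, h, 2, wd, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            # (Cin, 2, 2, Cout) -> (2, 2, Cin, Cout)
            dw = np.tensordot(x.data, gg, axes=([0, 1, 2], [0, 1, 2]))
            w._accum(dw.transpose(1, 2, 0, 3))
        if x.requires_grad:
            x._accum(np.tensordot(gg, w.data, axes=([3, 4, 5], [0, 1, 3])))

    return Tensor(out_data, parents=tuple(parents), backward=bw)


def maxpool_2x2(x):
    """2x2 max pooling with stride 2; ties share the gradient equally."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    r = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = r.max(axis=(2, 4))

    def bw(g):
        if not x.requires_grad:
            return
        omax = out_data[:, :, None, :, None, :]
        mask = (r == omax).astype(np.float32)
        mask /= mask.sum(axis=(2, 4), keepdims=True)
        gx = mask * g[:, :, None, :, None, :]
        x._accum(gx.reshape(n, h, w, c))

    return Tensor(out_data, parents=(x,), backward=bw)


def batchnorm_train(x, gamma, beta, eps=1e-5):
    """Batch normalisation over (N, H, W) per channel, training statistics.

    Returns (out, batch_mean, batch_var) with the statistics as plain
    arrays so the caller can maintain running averages.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 1, 2)
    m = float(np.prod([x.shape[a] for a in axes]))
    mu = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            s1 = dxhat.sum(axis=axes)
            s2 = (dxhat * xhat).sum(axis=axes)
            x._accum(inv_std / m * (m * dxhat - s1 - xhat * s2))

    out = Tensor(out_data, parents=(x, gamma, beta), backward=bw)
    return out, mu, var


def dropout(x, p, rng):
    """Inverted dropout with keep-probability 1-p."""
    x = as_tensor(x)
    if p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)
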