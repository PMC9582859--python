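"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
a backward closure per operation.  Only the operations needed by the
detection/segmentation networks are provided (elementwise arithmetic,
matmul, 2-D convolution, pooling, resizing, reductions, concat, softmax).
Gradient correctness is established by finite-difference tests rather than
by construction, so keep every backward rule boring and explicit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "global_avg_pool",
    "upsample_nearest2d",
    "resize_bilinear",
    "softmax",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "clip",
    "where_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] > 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        if isinstance(data, np.generic):       # numpy scalar: keep its dtype
            data = np.asarray(data)
        elif not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _ensure(other, self.data.dtype)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_ensure(other, self.data.dtype))

    def __rsub__(self, other):
        return _ensure(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _ensure(other, self.data.dtype)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure(other, self.data.dtype)
        out = _node(self.data / other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _ensure(other, self.data.dtype) / self

    def __pow__(self, exponent: float):
        out = _node(self.data ** exponent, (self,))
        if out._parents:
            def bw(g):
                self._accum(g * exponent * self.data ** (exponent - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _ensure(other, self.data.dtype)
        out = _node(self.data @ other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = _node(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            src_shape = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, src_shape).astype(self.data.dtype))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _ensure(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    parents = tuple(p for p in parents if p.requires_grad)
    out = Tensor(data, requires_grad=bool(parents))
    out._parents = parents
    return out


# -- nonlinearities ----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0), (x,))
    if out._parents:
        mask = x.data > 0
        out._backward = lambda g: x._accum(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,))
    if out._parents:
        out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = _node(e, (x,))
    if out._parents:
        out._backward = lambda g: x._accum(g * e)
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))
    if out._parents:
        out._backward = lambda g: x._accum(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through the interior."""
    out = _node(np.clip(x.data, lo, hi), (x,))
    if out._parents:
        mask = (x.data > lo) & (x.data < hi)
        out._backward = lambda g: x._accum(g * mask)
    return out


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where a constant boolean mask holds, else ``b``."""
    out = _node(np.where(mask, a.data, b.data), (a, b))
    if out._parents:
        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.where(mask, g, 0.0), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.where(mask, 0.0, g), b.data.shape))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _node(s, (x,))
    if out._parents:
        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))
        out._backward = bw
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tuple(tensors))
    if out._parents:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


# -- convolution -------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D convolution, NCHW layout.

    Supports dense (groups=1) and depthwise (groups == C_in == C_out)
    convolutions, which is all the architecture uses.  Implemented as a sum
    over kernel offsets so both directions map onto BLAS calls.
    """
    N, C, H, W = x.data.shape
    Co, Cg, kh, kw = w.data.shape
    s, p, d = stride, padding, dilation
    Ho = (H + 2 * p - d * (kh - 1) - 1) // s + 1
    Wo = (W + 2 * p - d * (kw - 1) - 1) // s + 1
    depthwise = groups != 1
    if depthwise and not (groups == C == Co and Cg == 1):
        raise ValueError("only dense or depthwise convolutions are supported")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out = np.zeros((N, Co, Ho, Wo), dtype=x.data.dtype)
    views = []
    for i in range(kh):
        row = []
        for j in range(kw):
            xs = xp[:, :, i * d: i * d + s * (Ho - 1) + 1: s,
                    j * d: j * d + s * (Wo - 1) + 1: s]
            row.append(xs)
            if depthwise:
                out += w.data[:, 0, i, j][None, :, None, None] * xs
            else:
                out += np.tensordot(xs, w.data[:, :, i, j],
                                    axes=([1], [1])).transpose(0, 3, 1, 2)
        views.append(row)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    res = _node(out, parents)
    if res._parents:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                dw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = views[i][j]
                        if depthwise:
                            dw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                        else:
                            dw[:, :, i, j] = np.tensordot(
                                g, xs, axes=([0, 2, 3], [0, 2, 3]))
                w._accum(dw)
            if x.requires_grad:
                dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        tgt = dxp[:, :, i * d: i * d + s * (Ho - 1) + 1: s,
                                  j * d: j * d + s * (Wo - 1) + 1: s]
                        if depthwise:
                            tgt += w.data[:, 0, i, j][None, :, None, None] * g
                        else:
                            tgt += np.tensordot(
                                g, w.data[:, :, i, j],
                                axes=([1], [0])).transpose(0, 3, 1, 2)
                x._accum(dxp[:, :, p: p + H, p: p + W] if p else dxp)
        res._backward = bw
    return res


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling with window = stride = k (shapes must divide)."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"max_pool2d: spatial size ({H},{W}) not divisible by {k}")
    Ho, Wo = H // k, W // k
    xr = x.data.reshape(N, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, Ho, Wo, k * k)
    idx = xr.argmax(axis=-1)
    out = _node(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], (x,))
    if out._parents:
        def bw(g):
            dxr = np.zeros((N, C, Ho, Wo, k * k), dtype=x.data.dtype)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            x._accum(dx.reshape(N, C, H, W))
        out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over H,W keeping (N, C, 1, 1)."""
    return x.mean(axis=(2, 3), keepdims=True)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    f = factor
    out = _node(x.data.repeat(f, axis=2).repeat(f, axis=3), (x,))
    if out._parents:
        N, C, H, W = x.data.shape

        def bw(g):
            x._accum(g.reshape(N, C, H, f, W, f).sum(axis=(3, 5)))
        out._backward = bw
    return out


_RESIZE_CACHE: dict = {}


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out x n_in), half-pixel centers."""
    key = (n_in, n_out, np.dtype(dtype).str)
    m = _RESIZE_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=dtype)
        scale = n_in / n_out
        src = (np.arange(n_out) + 0.5) * scale - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        lam = (src - lo).astype(dtype)
        m[np.arange(n_out), lo] += 1.0 - lam
        m[np.arange(n_out), hi] += lam
        _RESIZE_CACHE[key] = m
    return m


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Bilinear resize to ``out_hw``; separable dense matrices on each axis."""
    N, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    ry = _resize_matrix(H, Ho, x.data.dtype)
    rx = _resize_matrix(W, Wo, x.data.dtype)
    t = np.tensordot(x.data, ry, axes=([2], [1]))        # (N,C,W,Ho)
    y = np.tensordot(t, rx, axes=([2], [1]))             # (N,C,Ho,Wo)
    out = _node(y, (x,))
    if out._parents:
        def bw(g):
            t2 = np.tensordot(g, rx, axes=([3], [0]))    # (N,C,Ho,W)
            dx = np.tensordot(t2, ry, axes=([2], [0]))   # (N,C,W,H)
            x._accum(dx.transpose(0, 1, 3, 2))
        out._backward = bw
    return out
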