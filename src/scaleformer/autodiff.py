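"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is a classic dynamic tape: every operation returns a new
:class:`Tensor` holding the forward value plus a closure that maps the
output gradient onto the input gradients.  Only the primitives the
segmentation network needs are implemented — elementwise arithmetic,
(batched) matrix products, reductions, shape surgery, 2D convolutions
(dense and depthwise), pooling and bilinear resizing — all in float32.

A small multiply counter can be armed around a region of code to measure
how many attention-score multiplications a forward pass performs; the
attention blocks report into it.  This backs the empirical complexity
checks (s**4 scaling for grid attention, linear-in-N for channel
affinity) without any timing noise.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

DTYPE = np.float32

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "avg_pool2d",
    "resize_bilinear",
    "pad2d",
    "MultiplyCounter",
    "count_multiplies",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # ---- bookkeeping -------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autograd ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        grads = {id(self): np.asarray(grad, dtype=DTYPE)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if not (parent.requires_grad or parent._backward is not None
                        or parent._parents):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ---- arithmetic --------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        out._backward = lambda g: (_unbroadcast(g, self.data.shape),
                                   _unbroadcast(g, other.data.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        out._backward = lambda g: (_unbroadcast(g * other.data, self.data.shape),
                                   _unbroadcast(g * self.data, other.data.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def back(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / (other.data ** 2),
                                 other.data.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(np.matmul(self.data, other.data), (self, other))

        def back(g):
            ga = _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)),
                              self.data.shape)
            gb = _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g),
                              other.data.shape)
            return ga, gb
        out._backward = back
        return out

    # ---- elementwise nonlinearities ---------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = _node(val, (self,))
        out._backward = lambda g: (g * (0.5 / val),)
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        x = self.data
        val = np.empty_like(x)
        pos = x >= 0
        val[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        val[~pos] = ex / (1.0 + ex)
        out = _node(val, (self,))
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _node(val, (self,))
        out._backward = lambda g: (g * (1.0 - val * val),)
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0))).astype(DTYPE)
        pdf = (np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)).astype(DTYPE)
        out = _node(x * cdf, (self,))
        out._backward = lambda g: (g * (cdf + x * pdf),)
        return out

    # ---- reductions --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(DTYPE),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).astype(DTYPE),)
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape surgery ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: (g.reshape(src),)
        return out

    def swapaxes(self, a, b):
        out = _node(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        shape = self.data.shape

        def back(g):
            gx = np.zeros(shape, dtype=DTYPE)
            np.add.at(gx, idx, g)
            return (gx,)
        out._backward = back
        return out

    # ---- composite helpers ------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = np.asarray(data, dtype=DTYPE)
    out.requires_grad = False
    out.grad = None
    out._backward = None
    out._parents = parents
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


# ---------------------------------------------------------------------
# spatial primitives (inputs are [batch, channels, height, width])
# ---------------------------------------------------------------------

def _pad_index(n: int, pad: int, mode: str) -> np.ndarray:
    """Source index for each coordinate of an axis padded by ``pad`` on both
    sides.  ``edge`` clamps, ``wrap`` is circular."""
    idx = np.arange(-pad, n + pad)
    if mode == "edge":
        return np.clip(idx, 0, n - 1)
    if mode == "wrap":
        return idx % n
    raise ValueError(f"unknown pad mode {mode!r}")


def pad2d(x: Tensor, top: int, bottom: int, left: int, right: int,
          mode: str = "zero") -> Tensor:
    """Pad the two trailing axes.  Modes: zero, edge (replicate), wrap."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if mode == "zero":
        val = np.pad(x.data, ((0, 0), (0, 0), (top, bottom), (left, right)))
        out = _node(val, (x,))
        out._backward = lambda g: (g[:, :, top:top + H, left:left + W],)
        return out
    # gather formulation: padded[i, j] = x[ih[i], iw[j]]
    ih = np.concatenate([_pad_index(H, top, mode)[:top],
                         np.arange(H),
                         _pad_index(H, bottom, mode)[-bottom:] if bottom else
                         np.empty(0, dtype=int)])
    iw = np.concatenate([_pad_index(W, left, mode)[:left],
                         np.arange(W),
                         _pad_index(W, right, mode)[-right:] if right else
                         np.empty(0, dtype=int)])
    val = x.data[:, :, ih[:, None], iw[None, :]]
    out = _node(val, (x,))

    def back(g):
        gx = np.zeros((B, C, H, W), dtype=DTYPE)
        flat = (ih[:, None] * W + iw[None, :]).ravel()
        np.add.at(gx.reshape(B, C, H * W),
                  (slice(None), slice(None), flat),
                  g.reshape(B, C, -1))
        return (gx,)
    out._backward = back
    return out


def conv2d(x: Tensor, weight: Tensor, bias=None, stride: int = 1,
           padding: int = 0, pad_mode: str = "zero") -> Tensor:
    """Dense 2D convolution via im2col + GEMM.

    weight: [out_ch, in_ch, kh, kw]; bias: [out_ch] or None.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    if padding:
        x = pad2d(x, padding, padding, padding, padding, mode=pad_mode)
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # B,C,Ho,Wo,kh,kw
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, -1)
    val = (col @ wmat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, as_tensor(bias))
    if bias is not None:
        val = val + parents[2].data.reshape(1, O, 1, 1)
    out = _node(val, parents)

    def back(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, O)       # B*Ho*Wo, O
        gw = (gmat.T @ col).reshape(weight.data.shape)
        gcol = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
        gcol = gcol.transpose(0, 3, 1, 2, 4, 5)             # B,C,Ho,Wo,kh,kw
        gx = np.zeros((B, C, H, W), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + stride * Ho:stride,
                   j:j + stride * Wo:stride] += gcol[:, :, :, :, i, j]
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))
    out._backward = back
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias=None, stride: int = 1,
                     padding: int = 0, pad_mode: str = "zero") -> Tensor:
    """Depthwise 2D convolution; weight: [channels, kh, kw]."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    if padding:
        x = pad2d(x, padding, padding, padding, padding, mode=pad_mode)
    B, C, H, W = x.data.shape
    Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {Cw}")
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # B,C,Ho,Wo,kh,kw
    val = np.einsum("bchwij,cij->bchw", win, weight.data, optimize=True)
    parents = (x, weight) if bias is None else (x, weight, as_tensor(bias))
    if bias is not None:
        val = val + parents[2].data.reshape(1, C, 1, 1)
    out = _node(val, parents)

    def back(g):
        gw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)
        gx = np.zeros((B, C, H, W), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                    g * weight.data[:, i, j].reshape(1, C, 1, 1)
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))
    out._backward = back
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (spatial size must divide k)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: {H}x{W} not divisible by {k}")
    return (x.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5)))


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1D linear-interpolation matrix (half-pixel centers)."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(DTYPE)
    M[np.arange(n_out), lo] += 1.0 - frac
    M[np.arange(n_out), hi] += frac
    return M


_interp_cache: dict = {}


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the two trailing axes (half-pixel convention)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    kh, kw = (H, out_h), (W, out_w)
    if kh not in _interp_cache:
        _interp_cache[kh] = _interp_matrix(*kh)
    if kw not in _interp_cache:
        _interp_cache[kw] = _interp_matrix(*kw)
    Mh = Tensor(_interp_cache[kh])
    Mw = Tensor(_interp_cache[kw])
    return (Mh @ x) @ Mw.swapaxes(0, 1)


# ---------------------------------------------------------------------
# multiply counting (for empirical complexity laws)
# ---------------------------------------------------------------------

class MultiplyCounter:
    """Accumulates multiply counts reported by instrumented operations."""

    def __init__(self):
        self.count = 0

    def add(self, n: int):
        self.count += int(n)


_active_counters: list = []


class count_multiplies:
    """Context manager arming a :class:`MultiplyCounter`."""

    def __enter__(self) -> MultiplyCounter:
        self.counter = MultiplyCounter()
        _active_counters.append(self.counter)
        return self.counter

    def __exit__(self, *exc):
        _active_counters.remove(self.counter)
        return False


def report_multiplies(n: int):
    for c in _active_counters:
        c.add(n)
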