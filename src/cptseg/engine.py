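"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd tradition, but array-valued:
every :class:`Tensor` wraps an ``ndarray``, records its parents and a
backward closure, and ``Tensor.backward`` runs the tape in reverse
topological order.  All network code in this package is written against
these primitives, so analytic gradients are available everywhere without
hand-derived backward passes at the model level.

A process-global multiply-accumulate (MAC) counter can be armed with
:func:`count_macs`; the matmul/conv primitives then report their work,
tagged by category, which is what the accounting module consumes.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "count_macs",
    "erf",
    "exp",
    "gelu",
    "log",
    "matmul",
    "max_pool2d",
    "relu",
    "softmax",
    "sqrt",
    "upsample_bilinear",
]

DEFAULT_DTYPE = np.float64


# ---------------------------------------------------------------------------
# MAC counting
# ---------------------------------------------------------------------------

class MacCounter:
    """Accumulates multiply-accumulate counts by category during forwards."""

    def __init__(self) -> None:
        self.by_category: dict[str, int] = {}

    def add(self, category: str, macs: int) -> None:
        self.by_category[category] = self.by_category.get(category, 0) + int(macs)

    def total(self, categories: Iterable[str] | None = None) -> int:
        if categories is None:
            return sum(self.by_category.values())
        return sum(self.by_category.get(c, 0) for c in categories)


_ACTIVE_COUNTER: MacCounter | None = None


@contextlib.contextmanager
def count_macs():
    """Context manager arming a fresh MAC counter; yields the counter."""
    global _ACTIVE_COUNTER
    prev = _ACTIVE_COUNTER
    counter = MacCounter()
    _ACTIVE_COUNTER = counter
    try:
        yield counter
    finally:
        _ACTIVE_COUNTER = prev


def _record_macs(category: str, macs: int) -> None:
    if _ACTIVE_COUNTER is not None:
        _ACTIVE_COUNTER.add(category, macs)


_TRACING = False


@contextlib.contextmanager
def tracing():
    """Shape-only execution: matmul/conv return zeros without computing.

    Intended for MAC accounting of zero-initialized models, where every
    activation is exactly zero anyway; shapes and recorded MAC counts
    are identical to a real forward.  Backward is not supported inside.
    """
    global _TRACING
    prev = _TRACING
    _TRACING = True
    try:
        yield
    finally:
        _TRACING = prev


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (), backward=None):
        if isinstance(data, Tensor):
            data = data.data
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(DEFAULT_DTYPE)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad and not self._parents:
            return
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def _bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def _bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def _bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape))
        out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def _bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))
        out._backward = _bwd
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def _bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)
        out._backward = _bwd
        return out

    # -- reductions / reshapes ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def _bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out


# ---------------------------------------------------------------------------
# Elementwise / math ops
# ---------------------------------------------------------------------------

def exp(x: Tensor) -> Tensor:
    value = np.exp(x.data)
    out = Tensor(value, parents=(x,))
    # capture the array, not the tensor: a closure over `out` would make
    # every graph cyclic and defer freeing to the garbage collector
    out._backward = lambda g: x._accumulate(g * value)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    value = np.sqrt(x.data)
    out = Tensor(value, parents=(x,))
    out._backward = lambda g: x._accumulate(g * 0.5 / value)
    return out


def erf(x: Tensor) -> Tensor:
    from scipy.special import erf as _erf
    out = Tensor(_erf(x.data), parents=(x,))
    coeff = 2.0 / math.sqrt(math.pi)
    out._backward = lambda g: x._accumulate(g * coeff * np.exp(-x.data ** 2))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return x * (erf(x * (1.0 / math.sqrt(2.0))) + 1.0) * 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])
    out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# Linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor, category: str = "matmul") -> Tensor:
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    if _TRACING:
        shape = np.broadcast_shapes(a.shape[:-2], b.shape[:-2]) + (
            a.shape[-2], b.shape[-1])
        _record_macs(category, int(np.prod(shape)) * a.shape[-1])
        # no parents: traced graphs are never differentiated, and cutting
        # the chain here lets upstream intermediates be freed eagerly
        return Tensor(np.zeros(shape, dtype=a.dtype))
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))
    if _ACTIVE_COUNTER is not None:
        # MACs = product of output shape x inner dimension
        inner = a.data.shape[-1]
        _record_macs(category, int(np.prod(out.data.shape)) * inner)

    def _bwd(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))
    out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# Spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (B,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo, x.shape


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, category: str = "conv") -> Tensor:
    """2D convolution (cross-correlation) on NCHW input."""
    b, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    if _TRACING:
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wd + 2 * padding - kw) // stride + 1
        _record_macs(category, b * ho * wo * o * c * kh * kw)
        return Tensor(np.zeros((b, o, ho, wo), dtype=x.dtype))
    cols, ho, wo, padded_shape = _im2col(x.data, kh, kw, stride, padding)
    w2d = w.data.reshape(o, -1)
    y = cols @ w2d.T                            # (B*Ho*Wo, O)
    if bias is not None:
        y = y + bias.data
    y = y.reshape(b, ho, wo, o).transpose(0, 3, 1, 2)
    _record_macs(category, b * ho * wo * o * c * kh * kw)
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(y, parents=parents)

    def _bwd(g):
        gf = g.transpose(0, 2, 3, 1).reshape(b * ho * wo, o)
        w._accumulate((gf.T @ cols).reshape(w.shape))
        if bias is not None:
            bias._accumulate(gf.sum(axis=0))
        dcols = (gf @ w2d).reshape(b, ho, wo, c, kh, kw)
        dxp = np.zeros(padded_shape, dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)
    out._backward = _bwd
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    b, c, h, w = x.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xd.shape[2], xd.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(b, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))
    oh, ow = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
    ih = oh[None, None] * stride + idx // kernel      # (B,C,Ho,Wo)
    iw = ow[None, None] * stride + idx % kernel
    bi = np.arange(b)[:, None, None, None]
    cc = np.arange(c)[None, :, None, None]

    def _bwd(g):
        dxp = np.zeros((b, c, hp, wp), dtype=x.dtype)
        np.add.at(dxp, (np.broadcast_to(bi, idx.shape),
                        np.broadcast_to(cc, idx.shape), ih, iw), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)
    out._backward = _bwd
    return out


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize (half-pixel centers, like align_corners=False)."""
    b, c, h, w = x.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        return x

    def _axis(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        t = np.clip(src - i0, 0.0, 1.0)
        return i0, i1, t

    r0, r1, tr = _axis(h, ho)
    c0, c1, tc = _axis(w, wo)
    tr = tr[:, None]
    tc = tc[None, :]
    xd = x.data
    v = ((1 - tr) * (1 - tc) * xd[:, :, r0[:, None], c0[None, :]]
         + (1 - tr) * tc * xd[:, :, r0[:, None], c1[None, :]]
         + tr * (1 - tc) * xd[:, :, r1[:, None], c0[None, :]]
         + tr * tc * xd[:, :, r1[:, None], c1[None, :]])
    out = Tensor(v, parents=(x,))

    def _bwd(g):
        dx = np.zeros_like(x.data)
        rr0 = np.broadcast_to(r0[:, None], (ho, wo))
        rr1 = np.broadcast_to(r1[:, None], (ho, wo))
        cc0 = np.broadcast_to(c0[None, :], (ho, wo))
        cc1 = np.broadcast_to(c1[None, :], (ho, wo))
        for rows, cols_, wgt in (
                (rr0, cc0, (1 - tr) * (1 - tc)),
                (rr0, cc1, (1 - tr) * tc),
                (rr1, cc0, tr * (1 - tc)),
                (rr1, cc1, tr * tc)):
            np.add.at(dx, (slice(None), slice(None), rows, cols_), g * wgt)
        x._accumulate(dx)
    out._backward = _bwd
    return out
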