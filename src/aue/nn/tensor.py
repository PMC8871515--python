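"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tensor engine sized for the networks in this package: 4-D
(batch, channel, height, width) feature maps, 2-D convolutions, the
normalizations and gates the generator/discriminator need, and nothing
more.  All data is float32; gradients are accumulated into ``.grad`` by
:meth:`Tensor.backward` over a topologically sorted tape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "no_grad", "concat", "conv2d", "pad2d"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference / target tensors)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, True, parents, backward)
        return Tensor(data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- autodiff ------------------------------------------------------------

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = expit(self.data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope).astype(np.float32)

        def bwd(g):
            self._accum(g * scale)

        return Tensor._make(self.data * scale, (self,), bwd)

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        out_data = np.logaddexp(0.0, self.data)

        def bwd(g):
            self._accum(g * expit(self.data))

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        axes = self._norm_axes(axis)

        def bwd(g):
            self._accum(np.broadcast_to(self._restore(g, axes, keepdims), self.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        axes = self._norm_axes(axis)
        count = int(np.prod([self.data.shape[a] for a in axes])) if axes else self.data.size
        out_data = self.data.mean(axis=axis, keepdims=keepdims)

        def bwd(g):
            self._accum(
                np.broadcast_to(self._restore(g, axes, keepdims), self.data.shape) / count
            )

        return Tensor._make(out_data, (self,), bwd)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the first argmax."""
        am = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(am, axis), axis=axis)

        def bwd(g):
            gx = np.zeros_like(self.data)
            gk = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gx, np.expand_dims(am, axis), gk, axis=axis)
            self._accum(gx)

        return Tensor._make(
            out_data if keepdims else np.squeeze(out_data, axis), (self,), bwd
        )

    def _norm_axes(self, axis) -> tuple[int, ...]:
        if axis is None:
            return tuple(range(self.data.ndim))
        if isinstance(axis, int):
            axis = (axis,)
        return tuple(a % self.data.ndim for a in axis)

    def _restore(self, g: np.ndarray, axes: tuple[int, ...], keepdims: bool) -> np.ndarray:
        if keepdims:
            return g
        for a in sorted(axes):
            g = np.expand_dims(g, a)
        return g

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bwd)

    __matmul__ = matmul


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def pad2d(x: Tensor, pad: int | tuple[int, int], mode: str = "zeros") -> Tensor:
    """Pad the two trailing (spatial) axes of a 4-D tensor.

    ``pad`` is a single width or a (vertical, horizontal) tuple, applied
    symmetrically on each axis.
    """
    ph, pw = (pad, pad) if isinstance(pad, int) else pad
    if ph == 0 and pw == 0:
        return x
    b, c, h, w = x.data.shape
    if mode == "zeros":
        out_data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

        def bwd(g):
            x._accum(g[:, :, ph : ph + h, pw : pw + w])

        return Tensor._make(out_data, (x,), bwd)
    if mode == "reflect":
        idx = np.pad(
            np.arange(h * w).reshape(h, w), ((ph, ph), (pw, pw)), mode="reflect"
        ).ravel()
        out_data = x.data.reshape(b, c, h * w)[:, :, idx].reshape(
            b, c, h + 2 * ph, w + 2 * pw
        )

        def bwd(g):
            g2 = g.reshape(b * c, -1)
            gx = np.zeros((b * c, h * w), dtype=np.float32)
            for i in range(b * c):
                gx[i] = np.bincount(idx, weights=g2[i], minlength=h * w)
            x._accum(gx.reshape(b, c, h, w))

        return Tensor._make(out_data, (x,), bwd)
    raise ValueError(f"unknown pad mode {mode!r}")


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid cross-correlation of NCHW input with OIHW kernel."""
    s = stride
    bs, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ho = (h - kh) // s + 1
    wo = (wd - kw) // s + 1
    out = np.zeros((bs, o, ho, wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            xs = x.data[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
            # (O,C)·(B,C,Ho,Wo) summed over C
            out += np.tensordot(w.data[:, :, ki, kj], xs, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
        for ki in range(kh):
            for kj in range(kw):
                if w.requires_grad:
                    xs = x.data[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                    gw[:, :, ki, kj] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                if x.requires_grad:
                    gxs = np.tensordot(g, w.data[:, :, ki, kj], axes=([1], [0]))
                    gx[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                        gxs.transpose(0, 3, 1, 2)
                    )
        if x.requires_grad:
            x._accum(gx)
        if w.requires_grad:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, bwd)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    out_data = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bwd(g):
        x._accum(np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k))

    return Tensor._make(out_data, (x,), bwd)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    def bwd(g):
        x._accum(g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    ho, wo = size
    b, c, h, w = x.data.shape
    if (ho, wo) == (h, w):
        return x
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    out_data = np.einsum("hH,wW,bcHW->bchw", ah, aw, x.data, optimize=True)

    def bwd(g):
        x._accum(np.einsum("hH,wW,bchw->bcHW", ah, aw, g, optimize=True))

    return Tensor._make(out_data, (x,), bwd)
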