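"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the denoising networks and training losses
need: broadcast elementwise arithmetic, ReLU, 2-D convolution (stride 1,
'same' output, zero or reflect padding) implemented as im2col + BLAS matmul,
2x2 max pooling, nearest-neighbour 2x upsampling, channel concatenation,
reductions, and a frequency-domain penalty primitive.  Gradients are
accumulated by topological traversal of the recorded graph.

Arrays keep whatever float dtype they arrive with: networks train in
float32 for speed; gradient checks run in float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "no_grad", "as_tensor", "add", "sub", "mul", "div", "neg",
    "power", "absolute", "relu", "conv2d", "maxpool2", "upsample2",
    "concat", "reduce_sum", "reduce_mean", "focal_frequency",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / validation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_float(data) -> np.ndarray:
    d = np.asarray(data)
    if d.dtype.kind != "f":
        d = d.astype(np.float64)
    return d


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ---------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        """Wrap scalars in the tensor's own dtype to avoid upcasting."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        return add(self, self._coerce(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, self._coerce(other))

    def __rsub__(self, other):
        return sub(self._coerce(other), self)

    def __mul__(self, other):
        return mul(self, self._coerce(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, self._coerce(other))

    def __rtruediv__(self, other):
        return div(self._coerce(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None):
        return reduce_sum(self, axis)

    def mean(self, axis=None):
        return reduce_mean(self, axis)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = g.astype(t.data.dtype, copy=False)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or g is t.data else g
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(a.data / b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    exponent = float(exponent)

    def backward(g):
        _accumulate(a, g * exponent * np.power(a.data, exponent - 1.0))

    return _make(np.power(a.data, exponent), (a,), backward)


def absolute(a: Tensor) -> Tensor:
    s = np.sign(a.data)

    def backward(g):
        _accumulate(a, g * s)

    return _make(np.abs(a.data), (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def reduce_sum(a: Tensor, axis=None) -> Tensor:
    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.shape))
        else:
            _accumulate(a, np.broadcast_to(np.expand_dims(g, axis), a.shape))

    return _make(a.data.sum(axis=axis), (a,), backward)


def reduce_mean(a: Tensor, axis=None) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g / n, a.shape))
        else:
            _accumulate(a, np.broadcast_to(np.expand_dims(g / n, axis), a.shape))

    return _make(a.data.mean(axis=axis), (a,), backward)


# ---------------------------------------------------------------------------
# convolution and spatial ops (N, C, H, W layout)
# ---------------------------------------------------------------------------

def _pad_input(x: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    if mode == "zeros":
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    if mode == "reflect":
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="reflect")
    raise ValueError(f"unsupported padding mode: {mode!r}")


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: str = "reflect") -> Tensor:
    """2-D convolution (cross-correlation), stride 1, 'same' output.

    x: (N, C, H, W); w: (O, C, kh, kw) with odd kh, kw; b: (O,) or None.
    """
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel sides must be odd")
    ph, pw = kh // 2, kw // 2
    xp = _pad_input(x.data, ph, pw, padding)

    K = kh * kw
    cols = np.empty((N, C, K, H, W), dtype=x.data.dtype)
    idx = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, idx] = xp[:, :, i:i + H, j:j + W]
            idx += 1
    # (N*H*W, C*K) with (C, K) flattening matching w.reshape(O, C*K)
    cols_m = cols.transpose(0, 3, 4, 1, 2).reshape(N * H * W, C * K)
    wm = w.data.reshape(O, C * K).T
    out = cols_m @ wm
    out = out.reshape(N, H, W, O).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(N * H * W, O)
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = (cols_m.T @ gm).T.reshape(O, C, kh, kw)
            _accumulate(w, gw)
        if x.requires_grad:
            gcols = (gm @ wm.T).reshape(N, H, W, C, K).transpose(0, 3, 4, 1, 2)
            gxp = np.zeros_like(xp)
            k = 0
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + H, j:j + W] += gcols[:, :, k]
                    k += 1
            if ph == 0 and pw == 0:
                gx = gxp
            else:
                gx = gxp[:, :, ph:ph + H, pw:pw + W].copy()
                if padding == "reflect":
                    for r in range(ph):
                        gx[:, :, ph - r, :] += gxp[:, :, r, pw:pw + W]
                        gx[:, :, H - 2 - r + 0, :] += gxp[:, :, H + ph + r, pw:pw + W]
                    for c in range(pw):
                        gx[:, :, :, pw - c] += gxp[:, :, ph:ph + H, c]
                        gx[:, :, :, W - 2 - c] += gxp[:, :, ph:ph + H, W + pw + c]
                    # corners reflect twice (row and column); handle them
                    for r in range(ph):
                        for c in range(pw):
                            gx[:, :, ph - r, pw - c] += gxp[:, :, r, c]
                            gx[:, :, ph - r, W - 2 - c] += gxp[:, :, r, W + pw + c]
                            gx[:, :, H - 2 - r, pw - c] += gxp[:, :, H + ph + r, c]
                            gx[:, :, H - 2 - r, W - 2 - c] += gxp[:, :, H + ph + r, W + pw + c]
            _accumulate(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; ties split gradient evenly."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial sides")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5))

    def backward(g):
        mask = (xr == out[:, :, :, None, :, None])
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gr = g[:, :, :, None, :, None] * mask / counts
        _accumulate(x, gr.reshape(N, C, H, W))

    return _make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    N, C, H, W = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        _accumulate(x, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(out, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def crop2d(x: Tensor, margin: int) -> Tensor:
    """Remove a border of ``margin`` pixels from the last two axes."""
    if margin == 0:
        return x
    sl = (Ellipsis, slice(margin, -margin), slice(margin, -margin))

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        _accumulate(x, gx)

    return _make(x.data[sl], (x,), backward)


# ---------------------------------------------------------------------------
# frequency-domain penalty primitive
# ---------------------------------------------------------------------------

def focal_frequency(pred: Tensor, target: Tensor, exponent: float = 1.0,
                    frozen_weight: np.ndarray | None = None) -> Tensor:
    """Spectrum-weighted frequency-domain squared error.

    mean over all frequency samples of w * |F(pred) - F(target)|^2 with the
    weight w = |F(pred) - F(target)|^exponent normalised to max 1 per image
    and treated as a constant (stop-gradient) during backpropagation.
    FFTs use the unitary ("ortho") normalisation over the last two axes.
    """
    fp = np.fft.fft2(pred.data, axes=(-2, -1), norm="ortho")
    ft = np.fft.fft2(target.data, axes=(-2, -1), norm="ortho")
    d = fp - ft
    if frozen_weight is None:
        w = np.abs(d) ** float(exponent)
        peak = w.max(axis=(-2, -1), keepdims=True)
        w = np.divide(w, peak, out=np.zeros_like(w), where=peak > 0)
    else:
        w = frozen_weight
    m = d.size
    val = float((w * np.abs(d) ** 2).sum() / m)

    def backward(g):
        if pred.requires_grad:
            gp = (2.0 / m) * np.real(
                np.fft.ifft2(w * d, axes=(-2, -1), norm="ortho"))
            _accumulate(pred, g * gp)
        if target.requires_grad:
            gt = (-2.0 / m) * np.real(
                np.fft.ifft2(w * d, axes=(-2, -1), norm="ortho"))
            _accumulate(target, g * gt)

    return _make(np.asarray(val, dtype=pred.data.dtype), (pred, target), backward)


def ffl_weight(pred: np.ndarray, target: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """The (detached) spectrum weight used by :func:`focal_frequency`."""
    d = np.fft.fft2(pred, axes=(-2, -1), norm="ortho") - \
        np.fft.fft2(target, axes=(-2, -1), norm="ortho")
    w = np.abs(d) ** float(exponent)
    peak = w.max(axis=(-2, -1), keepdims=True)
    return np.divide(w, peak, out=np.zeros_like(w), where=peak > 0)
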