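"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains and profiles a small convolutional encoder-decoder on CPU,
so the engine only implements the operators that network needs: broadcasted
arithmetic, reductions, (dilated) 2-D convolution, 2x2 pooling, bilinear
resizing, batched matrix products, sigmoid/ReLU, concatenation and slicing.

Every differentiable value is a :class:`Tensor` holding a numpy array and,
after :meth:`Tensor.backward`, the gradient of a scalar loss with respect to
it.  The graph is define-by-run: each operation records its parents and a
closure that propagates the incoming gradient.

A module-level multiply-accumulate counter supports static complexity
profiling: while :func:`profiling` is active, convolution and matrix-product
operations add their MAC cost to the counter (normalisation, activations,
pooling and interpolation are excluded, the convention used by the common
FLOP profilers which report one MAC per FLOP).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "set_default_dtype",
    "get_default_dtype",
    "profiling",
    "mac_count",
    "concat",
    "sigmoid",
    "relu",
    "log",
    "clip",
    "conv2d",
    "avg_pool2",
    "max_pool2",
    "bilinear_resize",
    "matmul",
]

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype newly created tensors are cast to (float32 or float64)."""
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


class _MacCounter:
    __slots__ = ("active", "total")

    def __init__(self) -> None:
        self.active = False
        self.total = 0


_MACS = _MacCounter()


@contextlib.contextmanager
def profiling():
    """Context manager enabling the MAC counter; resets the tally on entry."""
    prev_active, prev_total = _MACS.active, _MACS.total
    _MACS.active, _MACS.total = True, 0
    try:
        yield _MACS
    finally:
        _MACS.active, _MACS.total = prev_active, prev_total


def mac_count() -> int:
    return _MACS.total


def _record_macs(n: int) -> None:
    if _MACS.active:
        _MACS.total += int(n)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        arr = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}{tag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

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

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __getitem__(self, idx):
        return _slice(self, idx)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _accumulate(t: Tensor, grad: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
    else:
        t.grad = t.grad + grad


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


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(grad):
        _accumulate(a, _unbroadcast(grad, a.data.shape))
        _accumulate(b, _unbroadcast(grad, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(grad):
        _accumulate(a, _unbroadcast(grad * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(grad * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent

    def backward(grad):
        _accumulate(a, grad * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape))

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.data.size / data.size

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape) / denom)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(grad):
        _accumulate(a, grad / a.data)

    return _make(data, (a,), backward)


def clip(a, low: float, high: float) -> Tensor:
    """Clamp values; gradient is passed through inside the interval only."""
    a = as_tensor(a)
    data = np.clip(a.data, low, high)
    mask = (a.data >= low) & (a.data <= high)

    def backward(grad):
        _accumulate(a, grad * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                    np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(grad):
        _accumulate(a, grad * data * (1.0 - data))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)
    mask = a.data > 0

    def backward(grad):
        _accumulate(a, grad * mask)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(grad):
        _accumulate(a, grad.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        _accumulate(a, grad.transpose(inv))

    return _make(data, (a,), backward)


def _slice(a: Tensor, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def backward(grad):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, grad)
        _accumulate(a, full)

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, grad[tuple(sl)])

    return _make(data, tuple(ts), backward)


# ---------------------------------------------------------------------------
# linear-algebra / convolution primitives
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Batched matrix product (numpy @ semantics); counted by the profiler."""
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data
    # MACs: product over the broadcast batch dims times M*K*N
    batch = int(np.prod(data.shape[:-2])) if data.ndim > 2 else 1
    _record_macs(batch * data.shape[-2] * a.data.shape[-1] * data.shape[-1])

    def backward(grad):
        ga = grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ grad
        _accumulate(a, _unbroadcast(ga, a.data.shape))
        _accumulate(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: tuple[int, int],
            dilation: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    ph, pw = pad
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    ho = h + 2 * ph - eh + 1
    wo = w + 2 * pw - ew + 1
    if ho < 1 or wo < 1:
        raise ValueError("convolution kernel larger than padded input")
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2, s3),
        writeable=False,
    )
    return cols, ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           dilation: int = 1, padding: int | tuple[int, int] | None = None) -> Tensor:
    """2-D cross-correlation, stride 1, zero padding (default: size-preserving)."""
    x, weight = as_tensor(x), as_tensor(weight)
    cout, cin, kh, kw = weight.data.shape
    if x.data.ndim != 4:
        raise ValueError("conv2d expects a (batch, channel, row, col) input")
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, kernel expects {cin}")
    if padding is None:
        padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
    elif isinstance(padding, int):
        padding = (padding, padding)

    cols, ho, wo = _im2col(x.data, kh, kw, padding, dilation)
    b = x.data.shape[0]
    cols2 = cols.reshape(b, cin * kh * kw, ho * wo)
    w2 = weight.data.reshape(cout, cin * kh * kw)
    out = np.einsum("oc,bcl->bol", w2, cols2, optimize=True)
    out = out.reshape(b, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    _record_macs(b * ho * wo * cin * kh * kw * cout)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad):
        g2 = grad.reshape(b, cout, ho * wo)
        gw = np.einsum("bol,bcl->oc", g2, cols2, optimize=True)
        _accumulate(weight, gw.reshape(weight.data.shape))
        if bias is not None:
            _accumulate(bias, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = np.einsum("oc,bol->bcl", w2, g2, optimize=True)
            gcols = gcols.reshape(b, cin, kh, kw, ho, wo)
            ph, pw = padding
            h, w = x.data.shape[2], x.data.shape[3]
            gx = np.zeros((b, cin, h + 2 * ph, w + 2 * pw), dtype=grad.dtype)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i * dilation:i * dilation + ho,
                       j * dilation:j * dilation + wo] += gcols[:, :, i, j]
            _accumulate(x, gx[:, :, ph:ph + h, pw:pw + w])

    return _make(out, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    data = x.data.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(grad):
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        _accumulate(x, g)

    return _make(data, (x,), backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties share the gradient equally."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 requires even spatial dimensions")
    windows = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    data = windows.max(axis=(3, 5))
    mask = windows == data[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def backward(grad):
        g = (mask / counts) * grad[:, :, :, None, :, None]
        _accumulate(x, g.reshape(b, c, h, w))

    return _make(data, (x,), backward)


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize, align_corners=False."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Separable bilinear interpolation to `size` (rows, cols)."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        return x
    rm = _resize_matrix(h, ho, x.data.dtype)
    cm = _resize_matrix(w, wo, x.data.dtype)
    data = np.einsum("oh,bchw,pw->bcop", rm, x.data, cm, optimize=True)

    def backward(grad):
        gx = np.einsum("oh,bcop,pw->bchw", rm, grad, cm, optimize=True)
        _accumulate(x, gx)

    return _make(data, (x,), backward)
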