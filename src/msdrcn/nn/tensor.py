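"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the network needs: broadcasted
arithmetic, dense matmul, im2col-based 2-D convolution with stride/padding/
dilation, max pooling, fused batch normalization, bilinear resampling via
separable interpolation matrices, soft thresholding, and a fused weighted
cross-entropy.  Each operation records a backward closure on a tape; calling
:meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients on every node, so gradients of intermediate feature
maps (needed for Grad-CAM) come for free.

Graph recording is skipped entirely when no input requires a gradient or when
inside :func:`no_grad`, so pure inference never caches im2col buffers.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "add",
    "mul",
    "minimum",
    "concat",
    "relu",
    "sigmoid",
    "absolute",
    "mean",
    "reduce_sum",
    "reshape",
    "linear",
    "conv2d",
    "maxpool2d",
    "batch_norm",
    "upsample_bilinear",
    "resize_matrix",
    "soft_threshold",
    "cross_entropy",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs overflow Python recursion
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.dtype)))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    """Create an op output, recording the tape entry only when needed."""
    record = is_grad_enabled() and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=record)
    if record:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided form
    d = x.data
    out_data = np.empty_like(d)
    pos = d >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    out_data[~pos] = e / (1.0 + e)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; gradient follows the smaller input (ties -> a)."""
    a, b = _wrap(a), _wrap(b)
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        a._accumulate(_unbroadcast(g * mask, a.shape))
        b._accumulate(_unbroadcast(g * ~mask, b.shape))

    return _make(out_data, (a, b), backward)


def absolute(x: Tensor) -> Tensor:
    out_data = np.abs(x.data)
    sign = np.sign(x.data)

    def backward(g):
        x._accumulate(g * sign)

    return _make(out_data, (x,), backward)


def _getitem(x: Tensor, idx) -> Tensor:
    out_data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    return _make(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(out_data, ts, backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.shape))

    return _make(out_data, (x,), backward)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod([x.shape[a] for a in np.atleast_1d(axis)])

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis=tuple(np.atleast_1d(axis)))
        x._accumulate(np.broadcast_to(gg, x.shape) / n)

    return _make(out_data, (x,), backward)


def reduce_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis=tuple(np.atleast_1d(axis)))
        x._accumulate(np.broadcast_to(gg, x.shape).astype(x.dtype))

    return _make(out_data, (x,), backward)


# -- dense / conv layers --------------------------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """y = x @ weight.T + bias, with x of shape (B, Cin), weight (Cout, Cin)."""
    out_data = x.data @ weight.data.T
    if bias is not None:
        out_data = out_data + bias.data

    def backward(g):
        x._accumulate(g @ weight.data)
        weight._accumulate(g.T @ x.data)
        if bias is not None:
            bias._accumulate(g.sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            out_h: int, out_w: int) -> np.ndarray:
    B, C = xp.shape[:2]
    cols = np.empty((B, C, kh, kw, out_h, out_w), dtype=xp.dtype)
    for ki in range(kh):
        hs = ki * dilation
        he = hs + (out_h - 1) * stride + 1
        for kj in range(kw):
            ws = kj * dilation
            we = ws + (out_w - 1) * stride + 1
            cols[:, :, ki, kj] = xp[:, :, hs:he:stride, ws:we:stride]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/dilation."""
    B, C, H, W = x.shape
    Cout, Cin, kh, kw = weight.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    eff_h = dilation * (kh - 1) + 1
    eff_w = dilation * (kw - 1) + 1
    out_h = (H + 2 * padding - eff_h) // stride + 1
    out_w = (W + 2 * padding - eff_w) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, dilation, out_h, out_w)
    colsm = cols.reshape(B, C * kh * kw, out_h * out_w)
    wm = weight.data.reshape(Cout, -1)
    out = np.matmul(wm, colsm)  # (B, Cout, L)
    if bias is not None:
        out += bias.data[:, None]
    out_data = out.reshape(B, Cout, out_h, out_w)

    def backward(g):
        go = g.reshape(B, Cout, out_h * out_w)
        weight._accumulate(
            np.matmul(go, colsm.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape))
        if bias is not None:
            bias._accumulate(go.sum(axis=(0, 2)))
        dcols = np.matmul(wm.T, go).reshape(B, C, kh, kw, out_h, out_w)
        dxp = np.zeros_like(xp)
        for ki in range(kh):
            hs = ki * dilation
            he = hs + (out_h - 1) * stride + 1
            for kj in range(kw):
                ws = kj * dilation
                we = ws + (out_w - 1) * stride + 1
                dxp[:, :, hs:he:stride, ws:we:stride] += dcols[:, :, ki, kj]
        dx = dxp[:, :, padding:padding + H, padding:padding + W] if padding else dxp
        x._accumulate(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    B, C, H, W = x.shape
    out_h = (H + 2 * padding - kernel) // stride + 1
    out_w = (W + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    cols = _im2col(xp, kernel, kernel, stride, 1, out_h, out_w)
    colsm = cols.reshape(B, C, kernel * kernel, out_h * out_w)
    arg = colsm.argmax(axis=2)
    out_data = np.take_along_axis(colsm, arg[:, :, None], axis=2)[:, :, 0].reshape(
        B, C, out_h, out_w)

    def backward(g):
        dcols = np.zeros_like(colsm)
        np.put_along_axis(dcols, arg[:, :, None],
                          g.reshape(B, C, 1, out_h * out_w), axis=2)
        dcols = dcols.reshape(B, C, kernel, kernel, out_h, out_w)
        dxp = np.zeros_like(xp)
        for ki in range(kernel):
            he = ki + (out_h - 1) * stride + 1
            for kj in range(kernel):
                we = kj + (out_w - 1) * stride + 1
                dxp[:, :, ki:he:stride, kj:we:stride] += dcols[:, :, ki, kj]
        dx = dxp[:, :, padding:padding + H, padding:padding + W] if padding else dxp
        x._accumulate(dx.astype(x.dtype))

    return _make(out_data, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, *, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Fused batch normalization over all axes except channel axis 1.

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training (exponential moving average, unbiased variance, as is standard).
    """
    axes = (0,) + tuple(range(2, x.ndim))
    shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    n = x.data.size // x.shape[1]
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        if n > 1:
            running_mean += momentum * (m - running_mean)
            running_var += momentum * (v * n / (n - 1) - running_var)
    else:
        m = running_mean
        v = running_var
    ivar = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(shape)) * ivar.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        dxhat = g * gamma.data.reshape(shape)
        if training:
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            dx = (dxhat - s1 / n - xhat * s2 / n) * ivar.reshape(shape)
        else:
            dx = dxhat * ivar.reshape(shape)
        x._accumulate(dx.astype(x.dtype))

    return _make(out_data, (x, gamma, beta), backward)


# -- resampling -----------------------------------------------------------

_RESIZE_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def resize_matrix(in_size: int, out_size: int, dtype=np.float64) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (out_size, in_size).

    Uses the half-pixel-center convention (align_corners=False) with edge
    clamping, so 2-D bilinear resize factorizes as ``Mr @ img @ Mc.T``.
    """
    key = (in_size, out_size, np.dtype(dtype).str)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    M = np.zeros((out_size, in_size), dtype=dtype)
    scale = in_size / out_size
    for i in range(out_size):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), in_size - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, in_size - 1)
        frac = src - lo
        M[i, lo] += 1.0 - frac
        M[i, hi] += frac
    _RESIZE_CACHE[key] = M
    return M


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor to (out_h, out_w)."""
    B, C, H, W = x.shape
    Mr = resize_matrix(H, out_h, x.dtype)
    Mc = resize_matrix(W, out_w, x.dtype)
    out_data = np.matmul(np.matmul(Mr, x.data), Mc.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(Mr.T, g), Mc))

    return _make(out_data, (x,), backward)


# -- shrinkage and loss ---------------------------------------------------

def soft_threshold(x: Tensor, tau: Tensor) -> Tensor:
    """Soft shrinkage: y = sign(x) * max(|x| - tau, 0), tau >= 0 broadcastable.

    The exact-equality band |x| <= tau maps to zero; the subgradient there is
    taken as zero for both arguments.
    """
    x, tau = _wrap(x), _wrap(tau)
    if np.any(tau.data < 0):
        raise ValueError("soft_threshold: tau must be non-negative")
    sign = np.sign(x.data)
    mag = np.abs(x.data) - tau.data
    active = mag > 0
    out_data = sign * np.where(active, mag, 0.0)

    def backward(g):
        x._accumulate((g * active).astype(x.dtype))
        tau._accumulate(_unbroadcast(-g * sign * active, tau.shape).astype(tau.dtype))

    return _make(out_data, (x, tau), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted softmax cross-entropy, averaged by total sample weight.

    Matches the standard weighted-CE convention: each sample contributes
    ``w[label] * (-log p[label])`` and the sum is divided by ``sum w[label]``,
    so on a balanced set with unit weights this is the plain mean loss.
    """
    labels = np.asarray(labels)
    B, K = logits.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    if class_weights is None:
        w = np.ones(B, dtype=logits.dtype)
    else:
        w = np.asarray(class_weights, dtype=logits.dtype)[labels]
    wsum = w.sum()
    loss = -(w * logp[np.arange(B), labels]).sum() / wsum

    def backward(g):
        onehot = np.zeros((B, K), dtype=logits.dtype)
        onehot[np.arange(B), labels] = 1.0
        dlogits = (p - onehot) * w[:, None] / wsum
        logits._accumulate(np.asarray(g) * dlogits)

    return _make(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
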