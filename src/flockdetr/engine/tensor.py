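"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every differentiable operation
builds a node holding its parents and a closure that scatters the output
gradient back to them.  Arrays are float32 throughout; gradients are
accumulated, so a tensor used twice receives the sum of both paths.

Multiply--accumulate (MAC) counting for profiling is woven into the two
primitives where essentially all detector compute lives (``conv2d`` and
``matmul``): inside a :func:`count_macs` context each call adds its
analytic MAC count (k_h*k_w*C_in/groups*C_out*H_out*W_out for a
convolution, prod(batch)*n*k*m for a matrix product) to the active
counter.
"""

from __future__ import annotations

import contextlib
import math
from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "count_macs",
    "no_grad",
]

_GRAD_ENABLED = [True]
_MAC_STACK: list[dict] = []


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


_FAST_PROFILE = [False]


@contextlib.contextmanager
def count_macs(fast: bool = False):
    """Context manager yielding a dict whose 'macs' entry accumulates
    analytic multiply--accumulate counts of all conv/matmul calls.

    With ``fast=True`` the heavy primitives skip the arithmetic and
    emit zero-filled outputs of the correct shape: MAC counts are pure
    shape arithmetic, so the totals are identical to a real forward.
    """
    rec = {"macs": 0}
    _MAC_STACK.append(rec)
    if fast:
        _FAST_PROFILE.append(True)
    try:
        yield rec
    finally:
        _MAC_STACK.pop()
        if fast:
            _FAST_PROFILE.pop()


def _add_macs(n: int) -> None:
    if _MAC_STACK:
        _MAC_STACK[-1]["macs"] += int(n)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(())[()])

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- graph bookkeeping --------------------------------------------
    def _make(self, out_data, parents, backward):
        out = Tensor(out_data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
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
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the closure to release intermediate buffers
                node._backward = None
                node._parents = ()

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- conveniences --------------------------------------------------
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return a._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return a._make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accum(g * (p * a.data ** (p - 1.0)))

    return a._make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return a._make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return a._make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - out_data * out_data))

    return a._make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return a._make(out_data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x)."""
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return a._make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return a._make(out_data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _wrap(a)
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out_data = np.where(a.data > 0, a.data, neg)

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.where(a.data > 0, 1.0, neg + alpha))

    return a._make(out_data, (a,), backward)


def softplus(a) -> Tensor:
    a = _wrap(a)
    out_data = np.logaddexp(0.0, a.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (1.0 + np.exp(-a.data)))

    return a._make(out_data, (a,), backward)


def clip(a, lo: float | None, hi: float | None) -> Tensor:
    """Clamp with pass-through gradient strictly inside the bounds."""
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        mask &= a.data > lo
    if hi is not None:
        mask &= a.data < hi

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return a._make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    return a._make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    take_a = a.data <= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    return a._make(out_data, (a, b), backward)


def gelu(a) -> Tensor:
    """tanh-approximated GELU."""
    a = _wrap(a)
    c = math.sqrt(2.0 / math.pi)
    inner = tanh(c * (a + 0.044715 * a * a * a))
    return 0.5 * a * (1.0 + inner)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

    return a._make(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    scale = a.data.size / max(out_data.size, 1)

    def backward(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            a._accum(np.broadcast_to(gg, a.data.shape) / scale)

    return a._make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(in_shape))

    return a._make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return a._make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return a._make(out_data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    dummy = tensors[0]
    return dummy._make(out_data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    if _FAST_PROFILE[-1]:
        out_shape = np.broadcast_shapes(a.data.shape[:-2], b.data.shape[:-2]) + (
            a.data.shape[-2], b.data.shape[-1])
        out_data = np.zeros(out_shape, dtype=np.float32)
    else:
        out_data = a.data @ b.data
    # analytic MACs: batch * n * k * m
    k = a.data.shape[-1]
    _add_macs(out_data.size * k)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return a._make(out_data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return a._make(out_data, (a,), backward)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    a = _wrap(a)
    if not training or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return mul(a, Tensor(mask))


# ---------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x, w, b=None, stride: int = 1, padding=0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    Supports groups == 1 (dense) and groups == C_in (depthwise with
    channel multiplier 1).  Implemented by accumulating one matrix
    product per kernel tap, which keeps peak memory low at detector
    input sizes.
    """
    x, w = _wrap(x), _wrap(w)
    B, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    ph, pw = _pair(padding)
    s = stride
    if groups == 1 and Cg != C:
        raise ValueError(f"conv2d: weight expects {Cg} input channels, got {C}")
    if groups not in (1, C):
        raise ValueError("conv2d supports groups in {1, C_in} only")
    depthwise = groups == C and groups > 1
    if depthwise and (Cg != 1 or O != C):
        raise ValueError("depthwise conv2d requires weight shape (C, 1, kh, kw)")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kh) // s + 1
    Wo = (W + 2 * pw - kw) // s + 1
    out = np.zeros((B, O, Ho, Wo), dtype=np.float32)

    slices = []
    if not _FAST_PROFILE[-1]:
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                slices.append((i, j))
                if depthwise:
                    out += xs * w.data[:, 0, i, j][None, :, None, None]
                else:
                    # (O,C) @ (B,C,Ho*Wo) -> (B,O,Ho*Wo)
                    out += (w.data[:, :, i, j] @ xs.reshape(B, C, -1)).reshape(B, O, Ho, Wo)
    _add_macs(kh * kw * (C // groups) * O * Ho * Wo * B)
    if b is not None:
        b = _wrap(b)
        out += b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for i, j in slices:
            xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
            if depthwise:
                if need_w:
                    gw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                if need_x:
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                        g * w.data[:, 0, i, j][None, :, None, None]
                    )
            else:
                gm = g.reshape(B, O, -1)
                if need_w:
                    # sum_b (O,HW) @ (HW,C)
                    gw[:, :, i, j] = np.einsum("boh,bch->oc", gm, xs.reshape(B, C, -1))
                if need_x:
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                        w.data[:, :, i, j].T @ gm
                    ).reshape(B, C, Ho, Wo)
        if need_w:
            w._accum(gw)
        if need_x:
            x._accum(gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp)

    return x._make(out, parents, backward)


def avg_pool2d(x, kernel: int, stride: int | None = None) -> Tensor:
    x = _wrap(x)
    s = stride or kernel
    B, C, H, W = x.data.shape
    Ho, Wo = (H - kernel) // s + 1, (W - kernel) // s + 1
    out = np.zeros((B, C, Ho, Wo), dtype=np.float32)
    for i in range(kernel):
        for j in range(kernel):
            out += x.data[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
    out /= kernel * kernel

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gk = g / (kernel * kernel)
            for i in range(kernel):
                for j in range(kernel):
                    gx[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gk
            x._accum(gx)

    return x._make(out, (x,), backward)


def upsample_nearest2x(x) -> Tensor:
    x = _wrap(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            B, C, H2, W2 = g.shape
            gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            x._accum(gx)

    return x._make(out_data, (x,), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """BatchNorm over (N, H, W) for NCHW input; running stats are plain
    numpy arrays mutated in-place in training mode."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (0, 2, 3)
    shape = (1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.data.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1.0, 1.0))
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(shape)
            if training:
                n = x.data.size / x.data.shape[1]
                gmean = gs.mean(axis=axes, keepdims=True)
                gxhat_mean = (gs * xhat).mean(axis=axes, keepdims=True)
                gx = (gs - gmean - xhat * gxhat_mean) * inv.reshape(shape)
            else:
                gx = gs * inv.reshape(shape)
            x._accum(gx.astype(np.float32))

    return x._make(out_data, (x, gamma, beta), backward)
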