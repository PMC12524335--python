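"""Polar linear-attention encoder stage and the baseline attention stage.

The encoder block replaces the softmax intra-scale interaction layer of
a hybrid-encoder detector on the stride-32 level.  One block runs four
sub-systems in a fixed order over tokens X (B, N, C), N = H*W:

    Z1 = X + Drop1(PolarAttention(X))      global recast, linear in N
    Z2 = DyT1(Z1)                          statistics-free normalization
    Z3 = Adapter1(Z2)                      multi-receptive-field adapter
    Z4 = Z3 + Drop2(DetailFFN(Z3))         high-frequency compensation
    Y  = Adapter2(DyT2(Z4))                second normalization + fusion

PolarAttention is kernelized linear attention whose nonnegative feature
map factors into a learnable radial (per-dimension magnitude) gain and
an angular (direction) projection:

    phi(z) = softplus(r) * (elu(z @ W_ang) + 1)
    out_i  = phi_q(q_i) (sum_j phi_k(k_j) v_j^T) / (phi_q(q_i) sum_j phi_k(k_j) + eps)

which costs O(N d^2) instead of O(N^2 d).  DynamicTanh is the
normalization-free per-channel transform g * tanh(a x) + h.  The
multi-scale adapter down-projects channels, runs depthwise 3/5/7 and
average-pool branches in parallel, fuses them with input-conditioned
simplex weights, and adds a scaled residual.  The detail FFN expands
channels, applies parallel depthwise 3x3/5x5 convolutions fused the
same way, and projects back.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .engine import nn
from .engine import tensor as T
from .engine.tensor import Tensor

__all__ = [
    "PolarEncoderConfig", "sincos_position_2d", "PolarLinearAttention",
    "DynamicTanh", "MultiScaleAdapter", "DetailFFN", "PolarEncoderLayer",
    "BaselineEncoderLayer", "flatten_map", "unflatten_map",
]


def flatten_map(x: Tensor) -> tuple[Tensor, tuple[int, int]]:
    """(B, C, H, W) -> ((B, N, C), (H, W)) with N = H*W."""
    b, c, h, w = x.shape
    return T.transpose(x.reshape((b, c, h * w)), (0, 2, 1)), (h, w)


def unflatten_map(tokens: Tensor, hw: tuple[int, int]) -> Tensor:
    b, n, c = tokens.shape
    h, w = hw
    if n != h * w:
        raise ValueError(f"token count {n} != H*W = {h * w}")
    return T.transpose(tokens, (0, 2, 1)).reshape((b, c, h, w))


def sincos_position_2d(h: int, w: int, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """2-D sinusoidal position embedding, (H*W, dim)."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    gw, gh = np.meshgrid(np.arange(w, dtype=np.float32),
                         np.arange(h, dtype=np.float32))
    pos_dim = dim // 4
    omega = 1.0 / (temperature ** (np.arange(pos_dim, dtype=np.float32) / pos_dim))
    out_w = gw.reshape(-1, 1) * omega
    out_h = gh.reshape(-1, 1) * omega
    return np.concatenate(
        [np.sin(out_w), np.cos(out_w), np.sin(out_h), np.cos(out_h)], axis=1
    ).astype(np.float32)


def sincos_xy(xy: np.ndarray, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of normalized (x, y) in [0,1]^2 -> (N, dim).

    Shared by memory tokens (grid centers) and decoder query references
    (box centers) so both sides of cross-attention use one geometry.
    """
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    pos_dim = dim // 4
    omega = 1.0 / (temperature ** (np.arange(pos_dim, dtype=np.float32) / pos_dim))
    ax = xy[:, 0:1].astype(np.float32) * (2.0 * np.pi) * omega
    ay = xy[:, 1:2].astype(np.float32) * (2.0 * np.pi) * omega
    return np.concatenate([np.sin(ax), np.cos(ax), np.sin(ay), np.cos(ay)],
                          axis=1).astype(np.float32)


def grid_centers(h: int, w: int) -> np.ndarray:
    """Normalized cell-center coordinates of an h x w grid, (h*w, 2)."""
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
    return np.stack([(gx.ravel() + 0.5) / w, (gy.ravel() + 0.5) / h], axis=1)


@dataclass(frozen=True)
class PolarEncoderConfig:
    embed_dim: int = 256
    num_heads: int = 8
    ffn_expansion: float = 2.0
    drop1: float = 0.0
    drop2: float = 0.0
    mona_kernels: tuple[int, ...] = (3, 5, 7)
    mona_ratio: float = 0.25
    dyt_alpha: float = 0.5
    gate_bottleneck: int = 4         # reduction inside dynamic fusion gates

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        for p in (self.drop1, self.drop2):
            if not 0.0 <= p < 1.0:
                raise ValueError("drop rates must be in [0, 1)")


class BranchGate(nn.Module):
    """Input-conditioned simplex weights over n parallel branches:
    GAP -> bottlenecked 1x1 map to n*C -> softmax across branches."""

    def __init__(self, channels: int, n_branches: int, bottleneck: int = 4):
        super().__init__()
        hidden = max(8, channels // bottleneck)
        self.n = n_branches
        self.c = channels
        self.squeeze = nn.Conv2d(channels, hidden, 1, padding=0, bias=True)
        self.expand = nn.Conv2d(hidden, n_branches * channels, 1, padding=0, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        u = x.mean(axis=(2, 3), keepdims=True)
        s = self.expand(T.silu(self.squeeze(u)))
        s = s.reshape((x.shape[0], self.n, self.c, 1, 1))
        return T.softmax(s, axis=1)


class PolarLinearAttention(nn.Module):
    """Kernelized linear attention with radial/angular feature maps."""

    def __init__(self, dim: int, num_heads: int, eps: float = 1e-6):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.h, self.dh, self.eps = num_heads, dim // num_heads, eps
        self.q_proj = nn.Linear(dim, dim)
        self.k_proj = nn.Linear(dim, dim)
        self.v_proj = nn.Linear(dim, dim)
        self.out_proj = nn.Linear(dim, dim)
        rng = np.random.default_rng(7)
        scale = (self.dh ** -0.5)
        self.q_angular = nn.Parameter(
            rng.standard_normal((self.h, self.dh, self.dh)).astype(np.float32) * scale)
        self.k_angular = nn.Parameter(
            rng.standard_normal((self.h, self.dh, self.dh)).astype(np.float32) * scale)
        self.q_radial = nn.Parameter(np.zeros((self.h, 1, self.dh), dtype=np.float32))
        self.k_radial = nn.Parameter(np.zeros((self.h, 1, self.dh), dtype=np.float32))

    def _split(self, x):
        b, n, _ = x.shape
        return T.transpose(x.reshape((b, n, self.h, self.dh)), (0, 2, 1, 3))

    def _feature(self, z, angular, radial):
        # z: (B, h, N, dh); angular: (h, dh, dh); radial: (h, 1, dh)
        ang = T.elu(T.matmul(z, angular)) + 1.0
        return T.softplus(radial) * ang

    def _features(self, x: Tensor, pos: Tensor | None):
        if x.shape[1] < 1:
            raise ValueError("empty token sequence")
        xq = x if pos is None else x + pos
        qf = self._feature(self._split(self.q_proj(xq)), self.q_angular, self.q_radial)
        kf = self._feature(self._split(self.k_proj(xq)), self.k_angular, self.k_radial)
        v = self._split(self.v_proj(x))
        return qf, kf, v

    @staticmethod
    def kernel_mix(qf: Tensor, kf: Tensor, v: Tensor, eps: float) -> Tensor:
        """Linear-cost attention mix: qf (.., N, d), kf (.., N, d), v (.., N, d)."""
        kv = T.matmul(T.transpose(kf, (0, 1, 3, 2)), v)          # (B,h,d,d)
        ksum = kf.sum(axis=2, keepdims=True)                     # (B,h,1,d)
        num = T.matmul(qf, kv)                                   # (B,h,N,d)
        den = (qf * ksum).sum(axis=-1, keepdims=True)            # (B,h,N,1)
        return num * T.power(den + eps, -1.0)

    @staticmethod
    def dense_mix(qf: Tensor, kf: Tensor, v: Tensor, eps: float) -> Tensor:
        """Explicit O(N^2) reference: A = normalize(qf kf^T), out = A v."""
        scores = T.matmul(qf, T.transpose(kf, (0, 1, 3, 2)))     # (B,h,N,N)
        den = scores.sum(axis=-1, keepdims=True) + eps
        return T.matmul(scores * T.power(den, -1.0), v)

    def forward(self, x: Tensor, pos: Tensor | None = None, dense: bool = False) -> Tensor:
        b, n, c = x.shape
        qf, kf, v = self._features(x, pos)
        mix = (self.dense_mix if dense else self.kernel_mix)(qf, kf, v, self.eps)
        out = T.transpose(mix, (0, 2, 1, 3)).reshape((b, n, c))
        return self.out_proj(out)


class DynamicTanh(nn.Module):
    """y = g * tanh(a * x) + h per channel; no batch statistics."""

    def __init__(self, channels: int, init_alpha: float = 0.5):
        super().__init__()
        self.alpha = nn.Parameter(np.array([init_alpha], dtype=np.float32))
        self.weight = nn.Parameter(np.ones(channels, dtype=np.float32))
        self.bias = nn.Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.tanh(x * self.alpha) * self.weight + self.bias


class MultiScaleAdapter(nn.Module):
    """Down-project, parallel depthwise + pooling branches, dynamic
    simplex fusion, up-project, scaled residual (works on tokens)."""

    def __init__(self, dim: int, kernels: tuple[int, ...] = (3, 5, 7),
                 ratio: float = 0.25, gate_bottleneck: int = 4):
        super().__init__()
        c = max(8, int(dim * ratio))
        self.down = nn.Conv2d(dim, c, 1, padding=0, bias=True)
        self.branches = nn.ModuleList(
            [nn.Conv2d(c, c, k, groups=c, bias=True) for k in kernels])
        self.n_branches = len(kernels) + 1          # + average-pool branch
        self.gate = BranchGate(c, self.n_branches, gate_bottleneck)
        self.up = nn.Conv2d(c, dim, 1, padding=0, bias=True)
        self.scale = nn.Parameter(np.array([1.0], dtype=np.float32))

    @staticmethod
    def _pool3(x: Tensor) -> Tensor:
        return T.avg_pool2d(_pad_hw(x, 1), 3, 1)

    def forward(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        x = unflatten_map(tokens, hw)
        z = T.silu(self.down(x))
        outs = [br(z) for br in self.branches] + [self._pool3(z)]
        w = self.gate(z)                               # (B, n, c, 1, 1)
        fused = outs[0] * w[:, 0]
        for i in range(1, self.n_branches):
            fused = fused + outs[i] * w[:, i]
        y = x + self.scale * self.up(fused)
        out, _ = flatten_map(y)
        return out


def _pad_hw(x: Tensor, p: int) -> Tensor:
    """Zero-pad H and W by p (differentiable via getitem-style scatter)."""
    b, c, h, w = x.shape
    data = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    data[:, :, p : p + h, p : p + w] = x.data

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, :, p : p + h, p : p + w])

    return x._make(data, (x,), backward)


class DetailFFN(nn.Module):
    """Channel expansion + parallel depthwise 3x3/5x5 dynamically fused,
    then projection; the surrounding residual lives in the caller."""

    def __init__(self, dim: int, expansion: float = 2.0, gate_bottleneck: int = 4):
        super().__init__()
        c = int(dim * expansion)
        self.expand = nn.Conv2d(dim, c, 1, padding=0, bias=True)
        self.dw3 = nn.Conv2d(c, c, 3, groups=c, bias=True)
        self.dw5 = nn.Conv2d(c, c, 5, groups=c, bias=True)
        self.gate = BranchGate(c, 2, gate_bottleneck)
        self.project = nn.Conv2d(c, dim, 1, padding=0, bias=True)

    def forward(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        x = unflatten_map(tokens, hw)
        z = T.gelu(self.expand(x))
        w = self.gate(z)
        fused = self.dw3(z) * w[:, 0] + self.dw5(z) * w[:, 1]
        out, _ = flatten_map(self.project(fused))
        return out


class PolarEncoderLayer(nn.Module):
    """The four-stage encoder block operating on a stride-32 feature map."""

    def __init__(self, cfg: PolarEncoderConfig):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.attn = PolarLinearAttention(d, cfg.num_heads)
        self.drop1 = nn.Dropout(cfg.drop1)
        self.dyt1 = DynamicTanh(d, cfg.dyt_alpha)
        self.mona1 = MultiScaleAdapter(d, cfg.mona_kernels, cfg.mona_ratio,
                                       cfg.gate_bottleneck)
        self.ffn = DetailFFN(d, cfg.ffn_expansion, cfg.gate_bottleneck)
        self.drop2 = nn.Dropout(cfg.drop2)
        self.dyt2 = DynamicTanh(d, cfg.dyt_alpha)
        self.mona2 = MultiScaleAdapter(d, cfg.mona_kernels, cfg.mona_ratio,
                                       cfg.gate_bottleneck)

    def forward(self, x: Tensor) -> Tensor:
        tokens, hw = flatten_map(x)
        pos = Tensor(sincos_position_2d(hw[0], hw[1], self.cfg.embed_dim))
        z1 = tokens + self.drop1(self.attn(tokens, pos))
        z2 = self.dyt1(z1)
        z3 = self.mona1(z2, hw)
        z4 = z3 + self.drop2(self.ffn(z3, hw))
        y = self.mona2(self.dyt2(z4), hw)
        return unflatten_map(y, hw)


class BaselineEncoderLayer(nn.Module):
    """Plain softmax-attention transformer layer (post-norm) on the
    stride-32 map -- the intra-scale stage of the baseline encoder."""

    def __init__(self, dim: int = 256, num_heads: int = 8,
                 ffn_dim: int = 1024, drop: float = 0.0):
        super().__init__()
        self.dim = dim
        self.attn = nn.MultiHeadAttention(dim, num_heads)
        self.drop = nn.Dropout(drop)
        self.norm1 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn_dim)
        self.fc2 = nn.Linear(ffn_dim, dim)
        self.norm2 = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        tokens, hw = flatten_map(x)
        pos = Tensor(sincos_position_2d(hw[0], hw[1], self.dim))
        qk = tokens + pos
        tokens = self.norm1(tokens + self.drop(self.attn(qk, qk, tokens)))
        tokens = self.norm2(tokens + self.drop(self.fc2(T.gelu(self.fc1(tokens)))))
        return unflatten_map(tokens, hw)
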