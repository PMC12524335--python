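"""Dynamic inception depthwise convolution and the mixing backbone built on it.

The operator runs three parallel depthwise branches over the input
feature map V (B, C, H, W):

    F1 = DWConv_{k x k}(V)          square branch
    F2 = DWConv_{1 x b}(V)          horizontal strip branch
    F3 = DWConv_{b x 1}(V)          vertical strip branch

with strip length ``b = 3k + 2`` so the strips respond to elongated
structures (stretched necks, partially occluded faces) that the square
kernel misses.  A global-context gate decides, per channel and per
sample, how much each branch contributes:

    U = GAP(V)                       (B, C, 1, 1)
    S = Conv1x1(U)                   (B, 3C, 1, 1)
    alpha_i = softmax_i(S_i)         simplex over the 3 branches

    Y = SiLU(BN(alpha1*F1 + alpha2*F2 + alpha3*F3))

Around the operator sit:

* :class:`GatedChannelMLP` -- a convolutional gated linear unit
  (pointwise expand x2, split into value/gate, depthwise-3x3 + sigmoid
  gate, pointwise project),
* :class:`InceptionMixer` -- a dual-residual token-mix / channel-mix
  unit with the dynamic inception conv as its token mixer,
* :class:`CSPMixBlock` -- a split/concat (C2f-style) block whose
  bottlenecks are :class:`InceptionMixer` units,
* :class:`Backbone` -- a four-stage feature extractor emitting
  stride-{8, 16, 32} maps for the encoder, configurable to use either
  the mixing blocks or plain residual blocks (the baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import nn
from .engine import tensor as T
from .engine.tensor import Tensor

__all__ = [
    "InceptionConvConfig", "BackboneConfig", "DynamicInceptionConv",
    "GatedChannelMLP", "InceptionMixer", "CSPMixBlock", "ResidualBlock",
    "Backbone", "build_backbone",
]


@dataclass(frozen=True)
class InceptionConvConfig:
    """Channel count and square-kernel size; the strip length is the
    derived quantity b = 3k + 2, never stored independently."""

    channels: int
    square_kernel: int = 3

    def __post_init__(self):
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.square_kernel <= 0 or self.square_kernel % 2 == 0:
            raise ValueError("square_kernel must be odd and positive "
                             f"(got {self.square_kernel})")

    @property
    def strip_length(self) -> int:
        return 3 * self.square_kernel + 2


class DynamicInceptionConv(nn.Module):
    """Three depthwise branches fused by input-conditioned simplex weights."""

    def __init__(self, cfg: InceptionConvConfig):
        super().__init__()
        self.cfg = cfg
        c, k, b = cfg.channels, cfg.square_kernel, cfg.strip_length
        self.square = nn.Conv2d(c, c, k, groups=c, bias=False)
        self.hstrip = nn.Conv2d(c, c, (1, b), groups=c, bias=False)
        self.vstrip = nn.Conv2d(c, c, (b, 1), groups=c, bias=False)
        self.gate = nn.Conv2d(c, 3 * c, 1, padding=0, bias=True)
        self.bn = nn.BatchNorm2d(c)

    def _check(self, x: Tensor):
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")

    def branches(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """The three shape-preserving depthwise branch outputs."""
        self._check(x)
        return self.square(x), self.hstrip(x), self.vstrip(x)

    def branch_weights(self, x: Tensor) -> Tensor:
        """Simplex weights of shape (B, 3, C, 1, 1): global average pool,
        1x1 map to 3C channels, softmax across the three segments."""
        self._check(x)
        u = x.mean(axis=(2, 3), keepdims=True)          # (B, C, 1, 1)
        s = self.gate(u)                                 # (B, 3C, 1, 1)
        bsz, c = x.shape[0], self.cfg.channels
        s = s.reshape((bsz, 3, c, 1, 1))
        return T.softmax(s, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        f1, f2, f3 = self.branches(x)
        a = self.branch_weights(x)
        mixed = a[:, 0] * f1 + a[:, 1] * f2 + a[:, 2] * f3
        return T.silu(self.bn(mixed))


class GatedChannelMLP(nn.Module):
    """Convolutional gated linear unit: expand x2, split value/gate,
    depthwise-3x3 + sigmoid on the gate, elementwise product, project."""

    def __init__(self, channels: int, expansion: float = 2.0):
        super().__init__()
        hidden = int(channels * expansion / 2)
        self.hidden = hidden
        self.expand = nn.Conv2d(channels, 2 * hidden, 1, padding=0, bias=True)
        self.gate_dw = nn.Conv2d(hidden, hidden, 3, groups=hidden, bias=True)
        self.project = nn.Conv2d(hidden, channels, 1, padding=0, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        vg = self.expand(x)
        value = vg[:, : self.hidden]
        gate = T.sigmoid(self.gate_dw(vg[:, self.hidden :]))
        return self.project(value * gate)


class InceptionMixer(nn.Module):
    """Dual-residual mixing unit: X + TokenMix(X), then + gated channel MLP."""

    def __init__(self, channels: int, square_kernel: int = 3,
                 mlp_expansion: float = 2.0):
        super().__init__()
        self.token_mix = DynamicInceptionConv(
            InceptionConvConfig(channels, square_kernel))
        self.channel_mix = GatedChannelMLP(channels, mlp_expansion)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.token_mix(x)
        return x + self.channel_mix(x)


class CSPMixBlock(nn.Module):
    """Split/concat block (C2f topology) with inception-mixer bottlenecks.

    cv1 projects to two hidden halves; ``depth`` mixer units chain off
    the second half, every intermediate is concatenated, and cv2 fuses
    back to ``cout`` channels.
    """

    def __init__(self, cin: int, cout: int, depth: int = 1,
                 hidden_ratio: float = 0.5, square_kernel: int = 3,
                 mlp_expansion: float = 2.0):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        h = max(8, int(cout * hidden_ratio))
        self.h = h
        self.cv1 = nn.ConvBNAct(cin, 2 * h, 1)
        self.bottlenecks = nn.ModuleList(
            [InceptionMixer(h, square_kernel, mlp_expansion) for _ in range(depth)])
        self.cv2 = nn.ConvBNAct((2 + depth) * h, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [y[:, : self.h], y[:, self.h :]]
        for m in self.bottlenecks:
            parts.append(m(parts[-1]))
        return self.cv2(T.concat(parts, axis=1))


class ResidualBlock(nn.Module):
    """Plain two-conv residual block (the baseline backbone unit); the
    inner width is ``channels * hidden_ratio``."""

    def __init__(self, channels: int, hidden_ratio: float = 1.0):
        super().__init__()
        h = max(8, int(channels * hidden_ratio))
        self.conv1 = nn.ConvBNAct(channels, h, 3)
        self.conv2 = nn.ConvBNAct(h, channels, 3, act=False)

    def forward(self, x: Tensor) -> Tensor:
        return T.silu(x + self.conv2(self.conv1(x)))


@dataclass(frozen=True)
class BackboneConfig:
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    stage_depths: tuple[int, int, int, int] = (1, 1, 2, 2)
    stem_channels: int = 32
    block: str = "mix"               # "mix" (inception mixers) or "residual"
    square_kernel: int = 3
    hidden_ratio: float = 0.5        # C2f split width, fraction of cout
    mlp_expansion: float = 2.0
    residual_hidden_ratio: float = 1.0   # inner width of plain residual blocks

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.stage_depths) != 4:
            raise ValueError("stage_channels and stage_depths must have 4 entries")
        if self.block not in ("mix", "residual"):
            raise ValueError(f"unknown block type {self.block!r}")
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("stage depths must be >= 1")


class Backbone(nn.Module):
    """Four-stage extractor; stage i sits at stride 2**(i+2) and the
    final three stages feed the encoder (strides 8, 16, 32)."""

    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        self.cfg = cfg
        cs = cfg.stage_channels
        self.stem = nn.Sequential(
            nn.ConvBNAct(3, cfg.stem_channels, 3, stride=2),
            nn.ConvBNAct(cfg.stem_channels, cs[0], 3, stride=2),
        )
        self.stages = nn.ModuleList()
        cin = cs[0]
        for i, (c, d) in enumerate(zip(cs, cfg.stage_depths)):
            layers = []
            if i > 0:
                layers.append(nn.ConvBNAct(cin, c, 3, stride=2))
            elif cin != c:
                layers.append(nn.ConvBNAct(cin, c, 1))
            if cfg.block == "mix":
                layers.append(CSPMixBlock(c, c, d, cfg.hidden_ratio,
                                          cfg.square_kernel, cfg.mlp_expansion))
            else:
                layers.extend(ResidualBlock(c, cfg.residual_hidden_ratio)
                              for _ in range(d))
            self.stages.append(nn.Sequential(*layers))
            cin = c

    @property
    def out_channels(self) -> tuple[int, int, int]:
        return tuple(self.cfg.stage_channels[1:])

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats[1:]          # strides 8, 16, 32


def build_backbone(cfg: BackboneConfig) -> Backbone:
    return Backbone(cfg)
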