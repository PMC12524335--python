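"""Detector configuration: dataclasses, named profiles, YAML round-trip.

The channel plan, block depths and encoder/decoder dimensions of the
default profiles were calibrated once against the architecture budgets
the toolkit targets and then frozen; they are plain data and can be
overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inception_conv import BackboneConfig
from .losses import LossWeights
from .polar_encoder import PolarEncoderConfig

__all__ = [
    "EncoderConfig", "DecoderConfig", "OptimizerConfig", "DetectorConfig",
    "default_config", "baseline_config", "backbone_only_config", "toy_config",
    "load_config", "save_config", "config_to_dict", "config_from_dict",
]


@dataclass(frozen=True)
class EncoderConfig:
    embed_dim: int = 256
    num_heads: int = 8
    variant: str = "polar"                 # "polar" or "baseline"
    aifi_ffn_dim: int = 1024
    ffn_expansion: float = 2.0             # polar-stage detail FFN
    drop1: float = 0.0
    drop2: float = 0.0
    mona_kernels: tuple[int, ...] = (3, 5, 7)
    mona_ratio: float = 0.25
    dyt_alpha: float = 0.5
    gate_bottleneck: int = 4
    fusion_depths: tuple[int, int, int, int] = (3, 3, 3, 3)  # td4, td3, bu4, bu5
    fusion_hidden: int | None = None       # residual width inside fusion

    def __post_init__(self):
        if self.variant not in ("polar", "baseline"):
            raise ValueError(f"unknown encoder variant {self.variant!r}")

    def polar_stage(self) -> PolarEncoderConfig:
        return PolarEncoderConfig(
            embed_dim=self.embed_dim, num_heads=self.num_heads,
            ffn_expansion=self.ffn_expansion, drop1=self.drop1,
            drop2=self.drop2, mona_kernels=self.mona_kernels,
            mona_ratio=self.mona_ratio, dyt_alpha=self.dyt_alpha,
            gate_bottleneck=self.gate_bottleneck)


@dataclass(frozen=True)
class DecoderConfig:
    num_queries: int = 300
    num_layers: int = 3
    num_heads: int = 8
    ffn_dim: int = 1024
    num_classes: int = 1


@dataclass(frozen=True)
class OptimizerConfig:
    name: str = "adamw"
    lr: float = 1e-4
    beta1: float = 0.9                     # "momentum" in the AdamW sense
    beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 8
    epochs: int = 150
    grad_clip: float = 0.1
    schedule: str = "constant"             # or "cosine"


@dataclass(frozen=True)
class DetectorConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    input_size: int = 640
    init_seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


# -- named profiles ---------------------------------------------------
# Depths and widths below were calibrated once against the architecture
# budgets this toolkit targets (see docs/methods.md) and then frozen.

_DEFAULT_BACKBONE = BackboneConfig(
    stage_channels=(64, 128, 256, 512), stage_depths=(1, 1, 2, 1),
    stem_channels=32, block="mix", square_kernel=3, hidden_ratio=0.5332)

_BASELINE_BACKBONE = BackboneConfig(
    stage_channels=(64, 128, 256, 512), stage_depths=(1, 3, 2, 1),
    stem_channels=85, block="residual", residual_hidden_ratio=1.043)

_FUSION = dict(fusion_depths=(0, 3, 0, 0), fusion_hidden=279)
_DECODER = DecoderConfig(num_queries=300, num_layers=3, num_heads=8,
                         ffn_dim=384)


def default_config(**overrides) -> DetectorConfig:
    """Full model: inception-mixing backbone + polar encoder + MAL."""
    cfg = DetectorConfig(
        backbone=_DEFAULT_BACKBONE,
        encoder=EncoderConfig(variant="polar", **_FUSION),
        decoder=_DECODER,
        loss=LossWeights(loss_type="mal"))
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def baseline_config(**overrides) -> DetectorConfig:
    """Baseline: plain residual backbone + softmax-attention encoder + VFL."""
    cfg = DetectorConfig(
        backbone=_BASELINE_BACKBONE,
        encoder=EncoderConfig(variant="baseline", aifi_ffn_dim=934, **_FUSION),
        decoder=_DECODER,
        loss=LossWeights(loss_type="vfl"))
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def backbone_only_config(**overrides) -> DetectorConfig:
    """Inception-mixing backbone with the baseline encoder and loss."""
    cfg = DetectorConfig(
        backbone=_DEFAULT_BACKBONE,
        encoder=EncoderConfig(variant="baseline", aifi_ffn_dim=934, **_FUSION),
        decoder=_DECODER,
        loss=LossWeights(loss_type="vfl"))
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def toy_config(input_size: int = 160, **overrides) -> DetectorConfig:
    """Reduced-width profile for CPU-scale experiments."""
    cfg = DetectorConfig(
        backbone=BackboneConfig(stage_channels=(16, 32, 48, 64),
                                stage_depths=(1, 1, 1, 1), stem_channels=8,
                                block="mix"),
        encoder=EncoderConfig(embed_dim=64, num_heads=4, aifi_ffn_dim=128,
                              fusion_depths=(1, 1, 1, 1), variant="polar"),
        decoder=DecoderConfig(num_queries=30, num_layers=2, num_heads=4,
                              ffn_dim=128),
        optimizer=OptimizerConfig(lr=1e-3, batch_size=8, epochs=15),
        input_size=input_size)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


# -- (de)serialization ------------------------------------------------

def config_to_dict(cfg: DetectorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # YAML-friendly: tuples to lists
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        return x
    return clean(d)


def _build(dc_type, data: dict):
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r} for {dc_type.__name__}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return dc_type(**kwargs)


def config_from_dict(data: dict) -> DetectorConfig:
    data = dict(data)
    bb = data.pop("backbone", {})
    if "didc_kernel" in bb:                   # external config alias
        bb["square_kernel"] = bb.pop("didc_kernel")
    enc = data.pop("encoder", {})
    loss = data.pop("loss", {})
    if "type" in loss:
        loss["loss_type"] = loss.pop("type")
    dec = data.pop("decoder", {})
    opt = data.pop("optimizer", {})
    return DetectorConfig(
        backbone=_build(BackboneConfig, bb),
        encoder=_build(EncoderConfig, enc),
        decoder=_build(DecoderConfig, dec),
        loss=_build(LossWeights, loss),
        optimizer=_build(OptimizerConfig, opt),
        **data)


def save_config(cfg: DetectorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> DetectorConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
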