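"""Model complexity profiling: trainable parameters, forward FLOPs, FPS.

FLOPs follow the multiply--accumulate convention dominant in detection
papers' "G" figures: one MAC per convolution tap per output element
(k_h * k_w * C_in / groups * C_out * H_out * W_out), one MAC per
element of every matrix product (attention cores included), elementwise
work not counted.  Counts are gathered analytically from the shapes
seen during a single forward pass at the stated input size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .engine import nn
from .engine import tensor as T
from .engine.tensor import Tensor

__all__ = ["ModelProfile", "count_params", "count_flops", "profile_model",
           "stage_param_table", "measure_fps"]


@dataclass
class ModelProfile:
    params_m: float                 # trainable parameters, millions
    flops_g: float                  # forward MACs, billions
    input_size: int
    convention: str = "multiply-accumulate (MAC) per-operator analytic count"
    t_pre_ms: float = 0.0
    t_inf_ms: float = 0.0
    t_nms_ms: float = 0.0           # always 0: the detector is NMS-free


def count_params(model: nn.Module) -> float:
    """Trainable parameter count in millions."""
    return model.num_params() / 1e6


def count_flops(model: nn.Module, input_size: int, fast: bool = True) -> float:
    """Forward MACs in billions at (1, 3, input_size, input_size).

    ``fast`` skips the arithmetic inside conv/matmul (counts are pure
    shape bookkeeping and identical either way).
    """
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    with T.no_grad(), T.count_macs(fast=fast) as rec:
        model(x)
    if was_training:
        model.train()
    return rec["macs"] / 1e9


def profile_model(model, input_size: int | None = None) -> ModelProfile:
    size = input_size or getattr(getattr(model, "cfg", None), "input_size", 640)
    return ModelProfile(params_m=count_params(model),
                        flops_g=count_flops(model, size),
                        input_size=size)


def stage_param_table(model) -> dict[str, float]:
    """Per-top-level-component parameter counts in millions."""
    table = {}
    for name, sub in model._modules.items():
        table[name] = sub.num_params() / 1e6
    return table


def measure_fps(model, input_size: int | None = None, n_warmup: int = 1,
                n_iter: int = 3) -> ModelProfile:
    """Wall-clock FPS measurement (hardware-dependent; never asserted)."""
    from .detector import preprocess_images  # local import, avoids cycle

    size = input_size or model.cfg.input_size
    rng = np.random.default_rng(0)
    raw = [(rng.random((size, size, 3)) * 255).astype(np.uint8)]
    model.eval()
    with T.no_grad():
        t0 = time.perf_counter()
        for _ in range(max(n_warmup + n_iter, 1)):
            x, _ = preprocess_images(raw, size)
        t_pre = (time.perf_counter() - t0) / max(n_warmup + n_iter, 1) * 1000
        model(x)  # warmup
        t0 = time.perf_counter()
        for _ in range(n_iter):
            model(x)
        t_inf = (time.perf_counter() - t0) / n_iter * 1000
    prof = profile_model(model, size)
    prof.t_pre_ms, prof.t_inf_ms, prof.t_nms_ms = t_pre, t_inf, 0.0
    return prof
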