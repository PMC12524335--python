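"""Neural-network module layer on top of the autodiff tensor engine.

Mirrors the familiar Module/Parameter idiom: modules own named
parameters and submodules, ``parameters()`` walks the tree,
``state_dict``/``load_state_dict`` give flat name->array checkpoints,
and ``train()``/``eval()`` toggle batch-norm and dropout behaviour.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "BatchNorm2d", "Linear", "LayerNorm", "Dropout",
    "SiLU", "ReLU", "GELU", "ConvBNAct",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_params(self) -> int:
        """Total trainable parameter element count."""
        return sum(p.size for p in self.parameters())

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- checkpointing -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            out["buffer:" + n] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, val in state.items():
            if key.startswith("buffer:"):
                b = bufs[key[7:]]
                np.copyto(b, val)
            else:
                p = params[key]
                if p.data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = val.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        name = str(len(self._list))
        self._list.append(m)
        self._modules[name] = m
        object.__setattr__(self, name, m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m
            object.__setattr__(self, str(i), m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)


class Identity(Module):
    def forward(self, x):
        return x


def kaiming(shape, fan_in, rng) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reset the parameter-initialisation stream (used by model builders)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=None, groups=1, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if padding is None:  # "same" for stride 1, halving for stride 2
            padding = (kh // 2, kw // 2)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = cin // groups * kh * kw
        self.weight = Parameter(kaiming((cout, cin // groups, kh, kw), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, cin, cout, bias=True):
        super().__init__()
        self.weight = Parameter(kaiming((cin, cout), cin, _INIT_RNG))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * T.power(var + self.eps, -0.5)
        return xhat * self.weight + self.bias


class Dropout(Module):
    _rng = np.random.default_rng(0)

    def __init__(self, p=0.0):
        super().__init__()
        self.p = p

    @classmethod
    def seed(cls, seed: int):
        cls._rng = np.random.default_rng(seed)

    def forward(self, x):
        return T.dropout(x, self.p, Dropout._rng, self.training)


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        # tanh approximation
        c = math.sqrt(2.0 / math.pi)
        return 0.5 * x * (1.0 + T.tanh(c * (x + 0.044715 * x * x * x)))


class MultiHeadAttention(Module):
    """Standard softmax attention; query/key/value are (B, N, C)."""

    def __init__(self, dim: int, num_heads: int):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.h = num_heads
        self.dh = dim // num_heads
        self.q_proj = Linear(dim, dim)
        self.k_proj = Linear(dim, dim)
        self.v_proj = Linear(dim, dim)
        self.out_proj = Linear(dim, dim)
        # zero-init residual output: the layer starts as identity, which
        # preserves per-token (and per-query) diversity early in training
        self.out_proj.weight.data[:] = 0.0

    def _split(self, x):
        b, n, _ = x.shape
        return T.transpose(x.reshape((b, n, self.h, self.dh)), (0, 2, 1, 3))

    def forward(self, q, k, v, bias=None):
        """Optional additive attention-logit bias (B, 1|h, Nq, Nk)."""
        b, nq, c = q.shape
        qh = self._split(self.q_proj(q)) * (self.dh ** -0.5)
        kh = self._split(self.k_proj(k))
        vh = self._split(self.v_proj(v))
        logits = T.matmul(qh, T.transpose(kh, (0, 1, 3, 2)))
        if bias is not None:
            logits = logits + bias
        attn = T.softmax(logits, axis=-1)
        out = T.transpose(T.matmul(attn, vh), (0, 2, 1, 3)).reshape((b, nq, c))
        return self.out_proj(out)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the detector's workhorse block."""

    def __init__(self, cin, cout, kernel=3, stride=1, groups=1, act=True, padding=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
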