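"""Network building blocks on top of the autodiff engine.

Modules hold named :class:`~fedct.autodiff.Tensor` parameters and expose
``named_parameters`` walkers so whole networks can be flattened into
:class:`~fedct.params.ParamSet` objects (the federation currency) and loaded
back bit-exactly.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .params import ParamSet


class Module:
    """Tiny module base: child modules and parameters become attributes."""

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Tensor]":
        out: "OrderedDict[str, Tensor]" = OrderedDict()
        for name, val in vars(self).items():
            path = f"{prefix}{name}" if prefix else name
            if isinstance(val, Tensor) and val.requires_grad:
                out[path] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(path + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{path}.{i}."))
        return out

    def get_paramset(self, role: str = "shared") -> ParamSet:
        return ParamSet({k: v.data.copy()
                         for k, v in self.named_parameters().items()}, role)

    def load_paramset(self, ps: ParamSet):
        params = self.named_parameters()
        if list(params.keys()) != list(ps.keys()):
            raise ValueError("parameter set does not match module layout")
        for k, t in params.items():
            if t.data.shape != ps[k].shape:
                raise ValueError(f"shape mismatch at {k!r}")
            t.data = np.asarray(ps[k], dtype=t.data.dtype).copy()

    def zero_grad(self):
        for t in self.named_parameters().values():
            t.zero_grad()

    def count_parameters(self) -> int:
        return int(sum(t.data.size for t in self.named_parameters().values()))


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel, stride: int = 1,
                 zero_init: bool = False):
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        if zero_init:
            w = np.zeros((out_ch, in_ch, kh, kw), dtype=np.float32)
        else:
            w = _kaiming(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = (kh // 2, kw // 2)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_f, out_f), dtype=np.float32)
        else:
            w = _kaiming(rng, (in_f, out_f), in_f)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + ad.reshape(self.bias, (1, -1))


class GroupNorm(Module):
    """Group normalisation with learnable per-channel scale and shift."""

    def __init__(self, n_channels: int, n_groups: int = 4, eps: float = 1e-5):
        if n_channels % n_groups != 0:
            n_groups = 1
        self.gamma = Tensor(np.ones(n_channels, dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=np.float32),
                           requires_grad=True)
        self.n_groups = n_groups
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.group_norm(x, self.gamma, self.beta, self.n_groups, self.eps)


class ChannelAttention(Module):
    """Squeeze-and-excitation: global average pool -> 2 FC -> sigmoid gate."""

    def __init__(self, rng, n_channels: int, reduction: int = 4):
        hidden = max(n_channels // reduction, 2)
        self.fc1 = Linear(rng, n_channels, hidden)
        self.fc2 = Linear(rng, hidden, n_channels)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        pooled = ad.reshape(ad.mean(x, axis=(2, 3)), (n, c))
        gate = ad.sigmoid(self.fc2(ad.leaky_relu(self.fc1(pooled))))
        return x * ad.reshape(gate, (n, c, 1, 1))


class SpatialAttention(Module):
    """Single-conv spatial gate: conv to one channel -> sigmoid -> multiply."""

    def __init__(self, rng, n_channels: int, kernel: int = 7):
        self.conv = Conv2d(rng, n_channels, 1, kernel)

    def __call__(self, x: Tensor) -> Tensor:
        return x * ad.sigmoid(self.conv(x))


def film_modulate(f: Tensor, v1: Tensor, v2: Tensor) -> Tensor:
    """Per-channel affine feature modulation ``f~ = V1 * f + V2``.

    ``v1``/``v2`` are (N, C) or (C,); broadcast over spatial positions.
    """
    c = f.shape[1]
    if v1.shape[-1] != c or v2.shape[-1] != c:
        raise ValueError(
            f"channel mismatch: features {c}, V1 {v1.shape[-1]}, V2 {v2.shape[-1]}")
    shape = (-1, c, 1, 1) if v1.ndim == 2 else (1, c, 1, 1)
    return f * ad.reshape(v1, shape) + ad.reshape(v2, shape)
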