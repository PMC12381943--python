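"""The three reconstruction networks.

* **TS-iRadonMAP** — the client-private dual-domain backbone: a 1x3-kernel
  residual sinogram network (Phi_s), a fixed differentiable back-projection
  layer (Phi_bp), and a 4-level U-Net image network (Phi_i).
* **Shared model** (Phi_m) — a lightweight image-to-image residual network
  with 7x7 kernels, spatial attention and per-unit conditional (FiLM)
  modulation; the only thing a client ever uploads.
* **Metamodel** (Phi_c) — architecturally identical to the shared model,
  trained on the server's metadata pool; its parameters anchor aggregation.

Both residual trunks end in zero-initialised convolutions wrapped in an outer
residual connection, so a freshly built network is the identity map: the
dual-domain model initially returns plain (or, optionally, filtered)
back-projection of its input.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ScanGeometry, bp_operator, fbp_operator
from .layers import (ChannelAttention, Conv2d, GroupNorm, Module,
                     SpatialAttention)
from .params import ParamSet
from .prompt import N_SLOTS, PromptNetwork


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults are the study-scale layout,
    channel widths are sized for CPU execution and scalable via config."""

    sinogram_units: int = 4
    image_depth: int = 4
    shared_units: int = 4
    base_channels: int = 32
    shared_channels: int = 32
    prompt_hidden: int = 16
    use_prompt: bool = True
    filtered_backprojection: bool = False
    groupnorm_groups: int = 4

    def __post_init__(self):
        for name in ("sinogram_units", "image_depth", "shared_units",
                     "base_channels", "shared_channels", "prompt_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def fingerprint(self) -> str:
        import hashlib
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Phi_s : sinogram-domain residual network (1x3 kernels, channel attention)
# ---------------------------------------------------------------------------

class SinogramNet(Module):
    """Residual 1x3-kernel network approximating the FBP filtering step."""

    def __init__(self, rng, cfg: ModelConfig):
        ch = cfg.base_channels
        g = cfg.groupnorm_groups
        self.head1 = Conv2d(rng, 1, ch, (1, 3))
        self.head_norm1 = GroupNorm(ch, g)
        self.head2 = Conv2d(rng, ch, ch, (1, 3))
        self.head_norm2 = GroupNorm(ch, g)
        self.units = [_SinoUnit(rng, ch, g) for _ in range(cfg.sinogram_units)]
        self.tail1 = Conv2d(rng, ch, ch, (1, 3))
        self.tail2 = Conv2d(rng, ch, 1, (1, 3), zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.head_norm1(self.head1(x)))
        h = ad.leaky_relu(self.head_norm2(self.head2(h)))
        for unit in self.units:
            h = unit(h)
        h = ad.leaky_relu(self.tail1(h))
        return x + self.tail2(h)


class _SinoUnit(Module):
    """Three residual conv blocks, channel attention after each block."""

    def __init__(self, rng, ch: int, groups: int):
        self.convs = [Conv2d(rng, ch, ch, (1, 3)) for _ in range(3)]
        self.norms = [GroupNorm(ch, groups) for _ in range(3)]
        self.attn = [ChannelAttention(rng, ch) for _ in range(3)]

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm, attn in zip(self.convs, self.norms, self.attn):
            x = x + attn(ad.leaky_relu(norm(conv(x))))
        return x


# ---------------------------------------------------------------------------
# Phi_i : image-domain U-Net
# ---------------------------------------------------------------------------

class _ConvBlock(Module):
    def __init__(self, rng, in_ch: int, out_ch: int):
        self.c1 = Conv2d(rng, in_ch, out_ch, 3)
        self.c2 = Conv2d(rng, out_ch, out_ch, 3)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(self.c2(ad.leaky_relu(self.c1(x))))


class UNet(Module):
    """Encoder-decoder with skip connections, strided down / nearest-up
    sampling, and a zero-initialised residual output head."""

    def __init__(self, rng, cfg: ModelConfig):
        depth = cfg.image_depth
        ch = cfg.base_channels
        widths = [ch * 2 ** i for i in range(depth)]
        self.enc = [_ConvBlock(rng, 1 if i == 0 else widths[i - 1], widths[i])
                    for i in range(depth)]
        self.down = [Conv2d(rng, widths[i], widths[i], 3, stride=2)
                     for i in range(depth - 1)]
        self.up = [Conv2d(rng, widths[i + 1], widths[i], 3)
                   for i in range(depth - 1)]
        self.dec = [_ConvBlock(rng, 2 * widths[i], widths[i])
                    for i in range(depth - 1)]
        self.out_conv = Conv2d(rng, widths[0], 1, 3, zero_init=True)
        self.depth = depth

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < self.depth - 1:
                skips.append(h)
                h = ad.leaky_relu(self.down[i](h))
        for i in reversed(range(self.depth - 1)):
            h = self.up[i](ad.upsample_nearest(h, 2))
            h = self.dec[i](ad.concat([h, skips[i]], axis=1))
        return x + self.out_conv(h)


# ---------------------------------------------------------------------------
# TS-iRadonMAP
# ---------------------------------------------------------------------------

class TSIRadonMAP(Module):
    """Dual-domain reconstructor: image = Phi_i(Phi_bp(Phi_s(sinogram))).

    Phi_bp is a fixed differentiable operator bound to the client geometry
    (no trainable parameters); its input gradient is the forward projector.
    """

    def __init__(self, geom: ScanGeometry, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sino_net = SinogramNet(rng, cfg)
        self.image_net = UNet(rng, cfg)
        if cfg.filtered_backprojection:
            self._bp, self._bp_t = fbp_operator(geom)
        else:
            self._bp, self._bp_t = bp_operator(geom)
        self.geometry = geom
        self.config = cfg

    def back_project(self, sino: Tensor) -> Tensor:
        return ad.linear_op(sino, self._bp, self._bp_t)

    def forward(self, sino: Tensor):
        """Returns (y_tilde, y): intermediate back-projection and output."""
        if sino.shape[2:] != (self.geometry.n_views, self.geometry.n_bins):
            raise ValueError(
                f"sinogram shape {sino.shape[2:]} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_bins})")
        filtered = self.sino_net(sino)
        y_tilde = self.back_project(filtered)
        y = self.image_net(y_tilde)
        return y_tilde, y

    __call__ = forward

    def paramsets(self):
        return {
            "sinogram_net": ParamSet(
                {k: v.data.copy()
                 for k, v in self.sino_net.named_parameters("sino_net.").items()},
                "sinogram_net"),
            "image_net": ParamSet(
                {k: v.data.copy()
                 for k, v in self.image_net.named_parameters("image_net.").items()},
                "image_net"),
        }


# ---------------------------------------------------------------------------
# Phi_m / Phi_c : lightweight shared model with conditional prompting
# ---------------------------------------------------------------------------

class _EnhancementUnit(Module):
    """Residual 7x7 conv block with spatial attention."""

    def __init__(self, rng, ch: int, kernel: int = 7):
        self.conv = Conv2d(rng, ch, ch, kernel)
        self.attn = SpatialAttention(rng, ch, kernel)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.attn(ad.leaky_relu(self.conv(x)))


class SharedModel(Module):
    """Image-to-image residual network, one FiLM modulation per unit.

    Used both as the client-side shared model (theta_m, theta_p) and as the
    server-side metamodel (theta_c, theta_p_c) — name/shape parity between
    the two is what makes Eq-style weighted aggregation well defined.
    """

    KERNEL = 7

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = cfg.shared_channels
        self.head = Conv2d(rng, 1, ch, self.KERNEL)
        self.units = [_EnhancementUnit(rng, ch, self.KERNEL)
                      for _ in range(cfg.shared_units)]
        self.tail = Conv2d(rng, ch, 1, self.KERNEL, zero_init=True)
        if cfg.use_prompt:
            self.prompt_net = PromptNetwork(rng, cfg.shared_units, ch,
                                            N_SLOTS, cfg.prompt_hidden)
        else:
            self.prompt_net = None
        self.config = cfg

    def forward(self, y_tilde: Tensor, cond: Tensor = None) -> Tensor:
        from .layers import film_modulate
        pairs = None
        if self.prompt_net is not None and cond is not None:
            pairs = self.prompt_net(cond)
        h = ad.leaky_relu(self.head(y_tilde))
        for i, unit in enumerate(self.units):
            h = unit(h)
            if pairs is not None:
                h = film_modulate(h, pairs[i][0], pairs[i][1])
        return y_tilde + self.tail(h)

    __call__ = forward

    def trunk_paramset(self, role: str = "shared") -> ParamSet:
        entries = {}
        for name in ("head", "units", "tail"):
            sub = getattr(self, name)
            if isinstance(sub, list):
                for i, m in enumerate(sub):
                    entries.update({k: v.data.copy() for k, v in
                                    m.named_parameters(f"{name}.{i}.").items()})
            else:
                entries.update({k: v.data.copy() for k, v in
                                sub.named_parameters(f"{name}.").items()})
        return ParamSet(entries, role)

    def prompt_paramset(self, role: str = "prompt") -> ParamSet:
        if self.prompt_net is None:
            return ParamSet({}, role)
        return ParamSet(
            {k: v.data.copy()
             for k, v in self.prompt_net.named_parameters("prompt_net.").items()},
            role)

    def load_trunk(self, ps: ParamSet):
        params = {}
        for name in ("head", "units", "tail"):
            sub = getattr(self, name)
            if isinstance(sub, list):
                for i, m in enumerate(sub):
                    params.update(m.named_parameters(f"{name}.{i}."))
            else:
                params.update(sub.named_parameters(f"{name}."))
        _load_into(params, ps)

    def load_prompt(self, ps: ParamSet):
        if self.prompt_net is None:
            if len(ps) == 0:
                return
            raise ValueError("cannot load prompt parameters: prompting disabled")
        _load_into(self.prompt_net.named_parameters("prompt_net."), ps)


def _load_into(params, ps: ParamSet):
    if list(params.keys()) != list(ps.keys()):
        raise ValueError("parameter set does not match module layout")
    for k, t in params.items():
        if t.data.shape != ps[k].shape:
            raise ValueError(f"shape mismatch at {k!r}")
        t.data = np.asarray(ps[k], dtype=t.data.dtype).copy()


# ---------------------------------------------------------------------------
# builders and checkpoints
# ---------------------------------------------------------------------------

def build_ts_iradonmap(geom: ScanGeometry, cfg: ModelConfig, seed: int = 0):
    """Returns (model, {'sinogram_net': ParamSet, 'image_net': ParamSet})."""
    model = TSIRadonMAP(geom, cfg, seed)
    return model, model.paramsets()


def build_shared_model(cfg: ModelConfig, seed: int = 0):
    """Returns (model, theta_m ParamSet, theta_p ParamSet)."""
    model = SharedModel(cfg, seed)
    return model, model.trunk_paramset("shared"), model.prompt_paramset("prompt")


def build_metamodel(cfg: ModelConfig, seed: int = 0):
    """Same graph as the shared model, separate parameters (theta_c)."""
    model = SharedModel(cfg, seed)
    return model, model.trunk_paramset("meta"), model.prompt_paramset("meta_prompt")


def count_parameters(obj) -> int:
    """Scalar parameter count of a Module or ParamSet."""
    if isinstance(obj, ParamSet):
        return obj.count_parameters()
    if isinstance(obj, Module):
        return obj.count_parameters()
    raise TypeError("expected a Module or ParamSet")


def save_checkpoint(directory: str, paramsets: dict, cfg: ModelConfig,
                    geom: ScanGeometry = None):
    """One container per role plus a manifest with config/geometry hashes."""
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "config_fingerprint": cfg.fingerprint(),
        "geometry_fingerprint": geom.fingerprint() if geom else None,
        "roles": list(paramsets.keys()),
    }
    for role, ps in paramsets.items():
        ps.save(os.path.join(directory, f"{role}.npz"))
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_checkpoint(directory: str, cfg: ModelConfig = None,
                    geom: ScanGeometry = None) -> dict:
    """Load role->ParamSet; refuses mismatched config or geometry."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if cfg is not None and manifest["config_fingerprint"] != cfg.fingerprint():
        raise ValueError("checkpoint was built with a different model config")
    if geom is not None and manifest["geometry_fingerprint"] is not None \
            and manifest["geometry_fingerprint"] != geom.fingerprint():
        raise ValueError("checkpoint was built with a different geometry")
    return {role: ParamSet.load(os.path.join(directory, f"{role}.npz"))
            for role in manifest["roles"]}
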