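"""Conditional prompting: acquisition parameters -> feature modulation.

A scanner geometry plus dose protocol is encoded into a fixed-layout
:class:`ConditionVector`; a shallow prompt network (three fully connected
layers per modulated unit) maps it to per-channel scale/shift pairs
``(V1, V2)`` that modulate feature maps as ``f~ = V1 * f + V2``.

Layout and normalisation are fixed across the whole federation: large
magnitudes (distances, counts, photon intensity) are log10-scaled, then each
slot is divided by a fixed reference constant so typical values land in
[0, 1].  Heterogeneous dose conditions occupy separate slots with a one-hot
condition-type indicator, so a view-count condition can never be confused
with a photon-intensity one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Linear, Module, film_modulate
from .lowdose import DoseProtocol
from .geometry import ScanGeometry

SLOT_NAMES = (
    "dsd", "dso", "n_views", "n_bins", "bin_len", "voxel_len",
    "is_low_mAs", "is_sparse_view", "is_limited_angle",
    "intensity", "views_kept_frac", "angular_span_frac", "region_code",
)

# reference divisors; log10 slots state the log10 of the reference value
SLOT_REFERENCE = {
    "dsd": 4.0,          # log10(mm) / 4
    "dso": 4.0,
    "n_views": 4.0,      # log10(count) / 4
    "n_bins": 4.0,
    "bin_len": 10.0,     # mm / 10
    "voxel_len": 10.0,
    "intensity": 6.0,    # log10(photons) / 6
    "region_code": 4.0,  # codes 1..4
}

N_SLOTS = len(SLOT_NAMES)


@dataclass(frozen=True)
class ConditionVector:
    values: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (N_SLOTS,):
            raise ValueError(f"condition vector must have {N_SLOTS} slots")
        if not np.all(np.isfinite(vals)):
            raise ValueError("condition vector contains non-finite entries")
        if np.any(vals < -1e-9) or np.any(vals > 1.0 + 1e-9):
            raise ValueError("condition vector entries must lie in [0, 1]")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float32)

    def __getitem__(self, name: str) -> float:
        return self.values[SLOT_NAMES.index(name)]


def encode_condition(geom: ScanGeometry, proto: DoseProtocol) -> ConditionVector:
    """Fixed-layout normalised encoding of (geometry, protocol)."""
    slots = np.zeros(N_SLOTS)

    def log_slot(value, ref):
        return math.log10(value) / ref if value and value > 0 else 0.0

    slots[0] = log_slot(geom.dsd, SLOT_REFERENCE["dsd"]) if geom.beam == "fanflat" else 0.0
    slots[1] = log_slot(geom.dso, SLOT_REFERENCE["dso"]) if geom.beam == "fanflat" else 0.0
    slots[2] = log_slot(geom.n_views, SLOT_REFERENCE["n_views"])
    slots[3] = log_slot(geom.n_bins, SLOT_REFERENCE["n_bins"])
    slots[4] = geom.bin_len / SLOT_REFERENCE["bin_len"]
    slots[5] = geom.voxel_len / SLOT_REFERENCE["voxel_len"]
    if proto.condition == "low_mAs":
        slots[6] = 1.0
        slots[9] = log_slot(proto.intensity_I0, SLOT_REFERENCE["intensity"])
    elif proto.condition == "sparse_view":
        slots[7] = 1.0
        slots[10] = proto.views_kept / geom.n_views if proto.views_kept else 0.0
    elif proto.condition == "limited_angle":
        slots[8] = 1.0
        slots[11] = proto.angular_span / (2.0 * math.pi)
    slots[12] = proto.region_code / SLOT_REFERENCE["region_code"]
    return ConditionVector(tuple(slots))


class ConditionalMappingUnit(Module):
    """Three fully connected layers producing one (V1, V2) pair.

    Identity initialisation: the final layer starts at zero weights with bias
    ``[1...1, 0...0]`` so V1 = 1 and V2 = 0 — training begins from an
    unmodulated network.
    """

    def __init__(self, rng, in_width: int, n_channels: int, hidden: int = 16):
        self.fc1 = Linear(rng, in_width, hidden)
        self.fc2 = Linear(rng, hidden, hidden)
        self.fc3 = Linear(rng, hidden, 2 * n_channels, zero_init=True)
        self.fc3.bias.data[:n_channels] = 1.0
        self.n_channels = n_channels

    def __call__(self, p: Tensor):
        h = ad.leaky_relu(self.fc1(p))
        h = ad.leaky_relu(self.fc2(h))
        out = self.fc3(h)
        c = self.n_channels
        v1 = _slice_axis1(out, 0, c)
        v2 = _slice_axis1(out, c, 2 * c)
        return v1, v2


def _slice_axis1(t: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(t.data[:, lo:hi], parents=(t,))

    def backward(g):
        gg = np.zeros_like(t.data)
        gg[:, lo:hi] = g
        ad._accum(t, gg)

    out._backward = backward
    return out


class PromptNetwork(Module):
    """One conditional mapping unit per modulated network layer."""

    def __init__(self, rng, n_units: int, n_channels: int,
                 in_width: int = N_SLOTS, hidden: int = 16):
        self.units = [ConditionalMappingUnit(rng, in_width, n_channels, hidden)
                      for _ in range(n_units)]
        self.in_width = in_width

    def __call__(self, p: Tensor):
        """Returns a list of (V1, V2) pairs, one per modulated unit."""
        if p.shape[-1] != self.in_width:
            raise ValueError(
                f"condition vector width {p.shape[-1]} != expected {self.in_width}")
        return [unit(p) for unit in self.units]


def prompt_forward(cond: ConditionVector, net: PromptNetwork):
    """Evaluate the prompt network on one condition vector.

    Returns a list of (V1, V2) numpy pairs (detached), one per unit.
    """
    p = Tensor(cond.as_array()[None, :])
    return [(v1.data[0].copy(), v2.data[0].copy()) for v1, v2 in net(p)]


def prompt_modulate(f: Tensor, v1, v2) -> Tensor:
    """Apply ``f~ = V1 * f + V2`` with per-channel broadcast."""
    v1 = v1 if isinstance(v1, Tensor) else Tensor(np.asarray(v1, dtype=np.float32))
    v2 = v2 if isinstance(v2, Tensor) else Tensor(np.asarray(v2, dtype=np.float32))
    return film_modulate(f, v1, v2)
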