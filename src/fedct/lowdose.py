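"""Low-dose acquisition simulation.

Ideal sinograms are degraded into the three canonical low-dose regimes:

* **low-mAs** — reduced tube current, modelled as monoenergetic Poisson
  statistics on the transmitted photon counts (``I0`` photons per ray);
* **sparse-view** — uniform subsampling of the projection views;
* **limited-angle** — restriction to a contiguous angular block.

All randomness flows through explicitly passed seeds; no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ScanGeometry, Sinogram

CONDITIONS = ("low_mAs", "sparse_view", "limited_angle", "none")

REGION_CODES = {"brain": 1, "abdomen": 2, "chest": 3, "phantom": 4}


@dataclass(frozen=True)
class DoseProtocol:
    """Sampling condition G plus anatomical region R of a client.

    Exactly the field relevant to ``condition`` is required:
    ``intensity_I0`` for low-mAs, ``views_kept`` for sparse-view,
    ``angular_span`` (radians) for limited-angle.
    """

    condition: str
    intensity_I0: Optional[float] = None
    views_kept: Optional[int] = None
    angular_span: Optional[float] = None
    angular_start: float = 0.0
    region_code: int = 1
    paired: bool = True

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "low_mAs":
            if self.intensity_I0 is None or self.intensity_I0 <= 0:
                raise ValueError("low_mAs requires intensity_I0 > 0")
        if self.condition == "sparse_view":
            if self.views_kept is None or self.views_kept < 1:
                raise ValueError("sparse_view requires views_kept >= 1")
        if self.condition == "limited_angle":
            if self.angular_span is None or self.angular_span <= 0:
                raise ValueError("limited_angle requires angular_span > 0")
        if not 1 <= self.region_code <= 4:
            raise ValueError("region_code must be in 1..4")

    def to_config(self) -> dict:
        block: dict = {"type": self.condition}
        if self.condition == "low_mAs":
            block["x_ray_intensity"] = self.intensity_I0
        elif self.condition == "sparse_view":
            block["sampling_views"] = self.views_kept
        elif self.condition == "limited_angle":
            block["sampling_angle"] = self.angular_span
            block["sampling_angle_start"] = self.angular_start
        return {
            "low_dose_protocol": block,
            "anatomical_region": self.region_code,
            "paired": self.paired,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DoseProtocol":
        block = cfg.get("low_dose_protocol", {"type": "none"})
        return cls(
            condition=block["type"],
            intensity_I0=block.get("x_ray_intensity"),
            views_kept=block.get("sampling_views"),
            angular_span=block.get("sampling_angle"),
            angular_start=block.get("sampling_angle_start", 0.0),
            region_code=cfg.get("anatomical_region", 1),
            paired=cfg.get("paired", True),
        )


def simulate_low_mAs(sino: Sinogram, I0: float, seed: int) -> Sinogram:
    """Photon-starved resampling of a line-integral sinogram.

    Transmitted counts per ray are Poisson with mean ``I0 * exp(-p)``; the
    returned sinogram is ``ln(I0 / max(count, 1))`` (count floor of one
    photon avoids log of zero).  Deterministic given ``seed``.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    p = sino.data
    if np.any(p < 0):
        raise ValueError("line integrals must be nonnegative")
    rng = np.random.default_rng(seed)
    mean_counts = I0 * np.exp(-p)
    counts = rng.poisson(mean_counts).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    return Sinogram(np.log(I0 / counts), sino.geometry)


def sparse_view_indices(n_views: int, views_kept: int) -> np.ndarray:
    """Uniform-stride view subset: ``round(i * n_views / views_kept)``."""
    idx = np.round(np.arange(views_kept) * n_views / views_kept).astype(int)
    if len(np.unique(idx)) != views_kept:
        raise ValueError("sparse-view rule produced duplicate indices")
    return idx


def subsample_views(sino: Sinogram, views_kept: int) -> Sinogram:
    """Keep ``views_kept`` views at uniform stride starting from index 0."""
    geom = sino.geometry
    if views_kept > geom.n_views:
        raise ValueError(
            f"views_kept={views_kept} exceeds n_views={geom.n_views}")
    idx = sparse_view_indices(geom.n_views, views_kept)
    return Sinogram(sino.data[idx].copy(), geom.with_views(idx))


def truncate_angles(sino: Sinogram, span: float, start: float = 0.0) -> Sinogram:
    """Keep the contiguous block of views with angles in [start, start+span)."""
    geom = sino.geometry
    angles = geom.angles
    full = angles[-1] - angles[0] + (angles[1] - angles[0] if geom.n_views > 1 else math.pi)
    if not 0 < span <= full + 1e-12:
        raise ValueError("span must be in (0, full coverage]")
    rel = np.mod(angles - start, 2.0 * math.pi)
    keep = np.where(rel < span - 1e-12)[0]
    if keep.size == 0:
        raise ValueError("angular truncation selected no views")
    return Sinogram(sino.data[keep].copy(), geom.with_views(keep))


def apply_protocol(sino: Sinogram, proto: DoseProtocol, seed: int) -> Sinogram:
    """Degrade an ideal sinogram according to a dose protocol."""
    if proto.condition == "low_mAs":
        return simulate_low_mAs(sino, proto.intensity_I0, seed)
    if proto.condition == "sparse_view":
        return subsample_views(sino, proto.views_kept)
    if proto.condition == "limited_angle":
        return truncate_angles(sino, proto.angular_span, proto.angular_start)
    return Sinogram(sino.data.copy(), sino.geometry)


def degraded_geometry(geom: ScanGeometry, proto: DoseProtocol) -> ScanGeometry:
    """Geometry of a sinogram after protocol degradation (view subsetting)."""
    if proto.condition == "sparse_view":
        return geom.with_views(sparse_view_indices(geom.n_views, proto.views_kept))
    if proto.condition == "limited_angle":
        angles = geom.angles
        rel = np.mod(angles - proto.angular_start, 2.0 * math.pi)
        keep = np.where(rel < proto.angular_span - 1e-12)[0]
        return geom.with_views(keep)
    return geom
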