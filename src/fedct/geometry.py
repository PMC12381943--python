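"""Virtual CT scan geometries and projection operators.

A :class:`ScanGeometry` describes a 2-D scanner: a square image grid, a set of
view angles, and a 1-D detector (parallel or fan-beam with a flat, equispaced
detector).  Projection is Joseph-style interpolating line integration,
materialised once per geometry as a ``scipy.sparse`` matrix so that the
back-projection used inside the networks is the *exact* transpose of the
forward operator.  Filtered back-projection (FBP) uses a separate
pixel-driven, distance-weighted back-projector with apodised ramp filtering
(Ram-Lak, Shepp-Logan, Hamming).

Conventions
-----------
* the image is centred at the isocenter; pixel centres sit at
  ``(i + 0.5 - n/2) * voxel_len``;
* view angles are radians, counterclockwise from the +x axis;
* sinograms are ``(n_views, n_bins)`` arrays of line integrals (unitless
  attenuation lengths, i.e. mm^-1 * mm);
* attenuation images are in mm^-1; HU conversion uses water at
  ``MU_WATER`` = 0.0192 mm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

MU_WATER = 0.0192  # mm^-1, configurable reference for HU conversion

FILTERS = ("ram-lak", "shepp-logan", "hamming")
BEAMS = ("parallel", "fanflat")


class GeometryError(ValueError):
    """Raised for inconsistent geometry definitions or mismatched shapes."""


def hu_to_mu(hu, mu_water: float = MU_WATER):
    """Hounsfield units -> linear attenuation (mm^-1); HU = 1000*(mu-muw)/muw."""
    return mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER):
    """Linear attenuation (mm^-1) -> Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=np.float64) - mu_water) / mu_water


def uniform_angles(n_views: int, span: float, start: float = 0.0) -> np.ndarray:
    """``n_views`` angles covering ``[start, start + span)`` uniformly."""
    return start + span * np.arange(n_views) / n_views


@dataclass(frozen=True)
class ScanGeometry:
    """Virtual scanner: grid, detector, trajectory and reconstruction filter."""

    n_voxels: int
    voxel_len: float
    n_views: int
    n_bins: int
    bin_len: float
    beam: str = "parallel"
    dsd: Optional[float] = None
    dso: Optional[float] = None
    view_angles: tuple = None  # radians, strictly increasing
    filter_name: str = "ram-lak"

    def __post_init__(self):
        if self.n_voxels < 1 or self.n_views < 1 or self.n_bins < 1:
            raise GeometryError("n_voxels, n_views and n_bins must be >= 1")
        if self.voxel_len <= 0 or self.bin_len <= 0:
            raise GeometryError("voxel_len and bin_len must be positive")
        if self.beam not in BEAMS:
            raise GeometryError(f"unknown beam type {self.beam!r}")
        if self.filter_name not in FILTERS:
            raise GeometryError(f"unknown filter {self.filter_name!r}")
        if self.view_angles is None:
            span = math.pi if self.beam == "parallel" else 2.0 * math.pi
            object.__setattr__(
                self, "view_angles", tuple(uniform_angles(self.n_views, span))
            )
        else:
            object.__setattr__(
                self, "view_angles", tuple(float(a) for a in self.view_angles)
            )
        if len(self.view_angles) != self.n_views:
            raise GeometryError("length of view_angles must equal n_views")
        diffs = np.diff(self.view_angles)
        if self.n_views > 1 and not np.all(diffs > 0):
            raise GeometryError("view_angles must be strictly increasing")
        if self.n_views > 1 and self.view_angles[-1] - self.view_angles[0] >= 2 * math.pi:
            raise GeometryError("view_angles must stay within one period")
        if self.beam == "fanflat":
            if self.dsd is None or self.dso is None:
                raise GeometryError("fanflat geometry requires dsd and dso")
            if not (self.dsd > self.dso > self.fov / 2.0):
                raise GeometryError("fanflat requires dsd > dso > fov/2")

    # -- derived quantities ------------------------------------------------
    @property
    def fov(self) -> float:
        """Field-of-view side length in mm."""
        return self.n_voxels * self.voxel_len

    @property
    def angles(self) -> np.ndarray:
        return np.asarray(self.view_angles, dtype=np.float64)

    @property
    def bin_centers(self) -> np.ndarray:
        """Detector bin centre coordinates (mm) along the detector axis."""
        return (np.arange(self.n_bins) + 0.5 - self.n_bins / 2.0) * self.bin_len

    def with_views(self, indices) -> "ScanGeometry":
        """Geometry restricted to a subset of views (sorted unique indices)."""
        indices = np.asarray(indices, dtype=int)
        angles = tuple(self.angles[indices])
        return replace(self, n_views=len(indices), view_angles=angles)

    def fingerprint(self) -> str:
        import hashlib
        key = repr((self.n_voxels, self.voxel_len, self.n_views, self.n_bins,
                    self.bin_len, self.beam, self.dsd, self.dso,
                    tuple(np.round(self.angles, 12)), self.filter_name))
        return hashlib.sha256(key.encode()).hexdigest()[:16]

    def to_config(self) -> dict:
        """Serialise with Table-style protocol vocabulary."""
        cfg = {
            "number_of_voxels": self.n_voxels,
            "length_of_voxel_mm": self.voxel_len,
            "number_of_projection_views": self.n_views,
            "number_of_detector_bins": self.n_bins,
            "length_of_detector_bin_mm": self.bin_len,
            "beam": self.beam,
            "reconstruction_filter": self.filter_name,
        }
        if self.beam == "fanflat":
            cfg["DSD_mm"] = self.dsd
            cfg["DSO_mm"] = self.dso
        cfg["view_angles_rad"] = [float(a) for a in self.view_angles]
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "ScanGeometry":
        angles = cfg.get("view_angles_rad")
        return cls(
            n_voxels=int(cfg["number_of_voxels"]),
            voxel_len=float(cfg["length_of_voxel_mm"]),
            n_views=int(cfg["number_of_projection_views"]),
            n_bins=int(cfg["number_of_detector_bins"]),
            bin_len=float(cfg["length_of_detector_bin_mm"]),
            beam=cfg.get("beam", "parallel"),
            dsd=cfg.get("DSD_mm"),
            dso=cfg.get("DSO_mm"),
            view_angles=tuple(angles) if angles is not None else None,
            filter_name=cfg.get("reconstruction_filter", "ram-lak"),
        )


@dataclass
class ImageGrid:
    """Square 2-D image with physical pixel size and value unit."""

    data: np.ndarray
    voxel_len: float
    value_unit: str = "mu"  # 'mu' (mm^-1) or 'HU'

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise GeometryError("ImageGrid must be square 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageGrid contains non-finite values")
        if self.value_unit not in ("mu", "HU"):
            raise ValueError(f"unknown value unit {self.value_unit!r}")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def to_mu(self, mu_water: float = MU_WATER) -> "ImageGrid":
        if self.value_unit == "mu":
            return self
        return ImageGrid(hu_to_mu(self.data, mu_water), self.voxel_len, "mu")

    def to_hu(self, mu_water: float = MU_WATER) -> "ImageGrid":
        if self.value_unit == "HU":
            return self
        return ImageGrid(mu_to_hu(self.data, mu_water), self.voxel_len, "HU")


@dataclass
class Sinogram:
    """(n_views, n_bins) line-integral array bound to its geometry."""

    data: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if self.data.shape != expected:
            raise GeometryError(
                f"sinogram shape {self.data.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")


# ---------------------------------------------------------------------------
# Sparse Joseph projector
# ---------------------------------------------------------------------------

_PROJECTOR_CACHE: dict = {}
_FBP_BP_CACHE: dict = {}


def _ray_endpoints(geom: ScanGeometry, view_idx: int):
    """Per-bin ray origin points and unit directions for one view."""
    theta = geom.angles[view_idx]
    s = geom.bin_centers
    if geom.beam == "parallel":
        # ray through s * (-sin, cos), direction (cos, sin)
        ox = -s * math.sin(theta)
        oy = s * math.cos(theta)
        dx = np.full_like(s, math.cos(theta))
        dy = np.full_like(s, math.sin(theta))
    else:
        # source at -dso*u, flat detector through +(dsd-dso)*u, axis v
        ux, uy = math.cos(theta), math.sin(theta)
        vx, vy = -math.sin(theta), math.cos(theta)
        sx = -geom.dso * ux
        sy = -geom.dso * uy
        px = (geom.dsd - geom.dso) * ux + s * vx
        py = (geom.dsd - geom.dso) * uy + s * vy
        dx = px - sx
        dy = py - sy
        norm = np.hypot(dx, dy)
        dx /= norm
        dy /= norm
        ox = np.full_like(s, sx)
        oy = np.full_like(s, sy)
    return ox, oy, dx, dy


def _joseph_view(geom: ScanGeometry, view_idx: int):
    """COO triplets (ray-local row = bin index, col = pixel, weight)."""
    n = geom.n_voxels
    d = geom.voxel_len
    ox, oy, dx, dy = _ray_endpoints(geom, view_idx)
    centers = (np.arange(n) + 0.5 - n / 2.0) * d  # pixel-centre coords

    rows_all, cols_all, w_all = [], [], []
    x_major = np.abs(dx) >= np.abs(dy)
    for major in (True, False):
        sel = np.where(x_major == major)[0]
        if sel.size == 0:
            continue
        o_m = (ox if major else oy)[sel]
        o_o = (oy if major else ox)[sel]
        d_m = (dx if major else dy)[sel]
        d_o = (dy if major else dx)[sel]
        # march along the major axis at each pixel-centre plane
        # t such that major coordinate == centers[j]
        t = (centers[None, :] - o_m[:, None]) / d_m[:, None]  # (nsel, n)
        other = o_o[:, None] + t * d_o[:, None]               # (nsel, n)
        frac = other / d + n / 2.0 - 0.5                      # fractional index
        i0 = np.floor(frac).astype(np.int64)
        a = frac - i0
        step = d / np.abs(d_m)                                 # path length
        for lo, wgt in ((i0, 1.0 - a), (i0 + 1, a)):
            valid = (lo >= 0) & (lo < n)
            if not valid.any():
                continue
            r, j = np.nonzero(valid)
            bins = sel[r]
            major_idx = j
            other_idx = lo[valid]
            if major:
                # major axis = x = column, other = y = row
                pix = other_idx * n + major_idx
            else:
                pix = major_idx * n + other_idx
            rows_all.append(bins)
            cols_all.append(pix)
            w_all.append(wgt[valid] * step[r])
    return (np.concatenate(rows_all), np.concatenate(cols_all),
            np.concatenate(w_all))


def system_matrix(geom: ScanGeometry) -> sp.csr_matrix:
    """Sparse forward projector, shape (n_views*n_bins, n_voxels**2)."""
    key = geom.fingerprint()
    mat = _PROJECTOR_CACHE.get(key)
    if mat is not None:
        return mat
    n_rays = geom.n_views * geom.n_bins
    rows, cols, ws = [], [], []
    for v in range(geom.n_views):
        r, c, w = _joseph_view(geom, v)
        rows.append(r + v * geom.n_bins)
        cols.append(c)
        ws.append(w)
    mat = sp.csr_matrix(
        (np.concatenate(ws), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rays, geom.n_voxels ** 2),
    )
    _PROJECTOR_CACHE[key] = mat
    return mat


def forward_project(image: ImageGrid, geom: ScanGeometry) -> Sinogram:
    """Line integrals of an attenuation image along every (view, bin) ray."""
    if image.value_unit != "mu":
        raise ValueError("forward_project expects an image in mu units")
    if image.n_voxels != geom.n_voxels:
        raise GeometryError(
            f"image side {image.n_voxels} does not match geometry {geom.n_voxels}"
        )
    if not np.all(np.isfinite(image.data)):
        raise ValueError("image contains non-finite values")
    A = system_matrix(geom)
    sino = (A @ image.data.ravel()).reshape(geom.n_views, geom.n_bins)
    return Sinogram(sino, geom)


def back_project(sino: Sinogram, geom: ScanGeometry) -> ImageGrid:
    """Adjoint of :func:`forward_project`, scaled by pi/(n_views*voxel_len).

    This is the fixed differentiable operator used inside the dual-domain
    networks: the derivative of ``back_project`` w.r.t. its input is the
    forward projector times the same constant.
    """
    if sino.geometry.fingerprint() != geom.fingerprint():
        raise GeometryError("sinogram geometry does not match")
    A = system_matrix(geom)
    scale = math.pi / (geom.n_views * geom.voxel_len)
    img = (A.T @ sino.data.ravel()).reshape(geom.n_voxels, geom.n_voxels)
    return ImageGrid(img * scale, geom.voxel_len, "mu")


# ---------------------------------------------------------------------------
# Filtered back-projection
# ---------------------------------------------------------------------------

def ramp_filter_response(n: int, spacing: float, filter_name: str) -> np.ndarray:
    """Frequency response (length ``n``) of the apodised ramp filter.

    Built from the band-limited spatial-domain ramp kernel so the DC term is
    handled correctly, then multiplied by the apodisation window.
    """
    if filter_name not in FILTERS:
        raise GeometryError(f"unknown filter {filter_name!r}")
    h = np.zeros(n)
    k = np.arange(n)
    kk = np.where(k <= n // 2, k, k - n)  # signed sample index with wraparound
    h[kk == 0] = 1.0 / (4.0 * spacing ** 2)
    odd = kk % 2 == 1
    h[odd] = -1.0 / (math.pi * kk[odd] * spacing) ** 2
    H = np.real(np.fft.fft(h))
    freq = np.fft.fftfreq(n, d=spacing)
    f_nyq = 1.0 / (2.0 * spacing)
    x = np.clip(np.abs(freq) / f_nyq, 0.0, 1.0)
    if filter_name == "shepp-logan":
        window = np.sinc(x / 2.0)
    elif filter_name == "hamming":
        window = 0.54 + 0.46 * np.cos(math.pi * x)
    else:
        window = np.ones_like(x)
    return H * window


def filter_sinogram(sino_data: np.ndarray, spacing: float,
                    filter_name: str) -> np.ndarray:
    """Apodised ramp filtering along the bin axis (zero-padded FFT)."""
    n_bins = sino_data.shape[-1]
    n_fft = 1 << int(np.ceil(np.log2(max(2 * n_bins, 16))))
    H = ramp_filter_response(n_fft, spacing, filter_name)
    spec = np.fft.fft(sino_data, n=n_fft, axis=-1) * H
    filt = np.real(np.fft.ifft(spec, axis=-1))[..., :n_bins]
    return filt * spacing


def _fbp_backprojector(geom: ScanGeometry) -> sp.csr_matrix:
    """Pixel-driven weighted back-projector (n_voxels^2, n_views*n_bins).

    Includes the angular step, the half factor for >pi coverage, and the
    fan-beam 1/U^2 magnification weight.  Combined with
    :func:`filter_sinogram` (applied on isocenter-rescaled bins for fan
    beams) this yields quantitative FBP.
    """
    key = geom.fingerprint()
    mat = _FBP_BP_CACHE.get(key)
    if mat is not None:
        return mat
    n = geom.n_voxels
    centers = (np.arange(n) + 0.5 - n / 2.0) * geom.voxel_len
    X, Y = np.meshgrid(centers, centers)  # X varies along columns
    x = X.ravel()
    y = Y.ravel()

    angles = geom.angles
    if geom.n_views > 1:
        dtheta = (angles[-1] - angles[0]) / (geom.n_views - 1)
    else:
        dtheta = math.pi
    coverage = angles[-1] - angles[0] + dtheta
    half = 0.5 if coverage > math.pi * 1.01 else 1.0

    rows, cols, ws = [], [], []
    pix_idx = np.arange(n * n)
    for v, theta in enumerate(angles):
        if geom.beam == "parallel":
            s = x * math.cos(theta) + y * math.sin(theta)
            w_pix = np.full(n * n, dtheta * half)
            frac = s / geom.bin_len + geom.n_bins / 2.0 - 0.5
        else:
            # isocenter-rescaled flat detector
            dso = geom.dso
            proj_u = x * math.cos(theta) + y * math.sin(theta)
            proj_v = -x * math.sin(theta) + y * math.cos(theta)
            U = (dso + proj_u) / dso
            s_iso = dso * proj_v / (dso + proj_u)
            bin_len_iso = geom.bin_len * dso / geom.dsd
            w_pix = dtheta * half / U ** 2
            frac = s_iso / bin_len_iso + geom.n_bins / 2.0 - 0.5
        i0 = np.floor(frac).astype(np.int64)
        a = frac - i0
        for lo, wgt in ((i0, 1.0 - a), (i0 + 1, a)):
            valid = (lo >= 0) & (lo < geom.n_bins)
            if not valid.any():
                continue
            rows.append(pix_idx[valid])
            cols.append(v * geom.n_bins + lo[valid])
            ws.append((wgt * w_pix)[valid])
    mat = sp.csr_matrix(
        (np.concatenate(ws), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, geom.n_views * geom.n_bins),
    )
    _FBP_BP_CACHE[key] = mat
    return mat


def fbp_reconstruct(sino: Sinogram, geom: ScanGeometry,
                    filter_name: Optional[str] = None) -> ImageGrid:
    """Filtered back-projection; output in mu units.

    Parallel beams use the classic ramp-filter + back-projection formula;
    flat fan beams rescale bins to the isocenter, cosine-weight the rays,
    filter, and back-project with the 1/U^2 magnification weight.
    """
    if sino.geometry.fingerprint() != geom.fingerprint():
        raise GeometryError("sinogram geometry does not match")
    filter_name = filter_name or geom.filter_name
    if filter_name not in FILTERS:
        raise GeometryError(f"unknown filter {filter_name!r}")
    data = sino.data
    if geom.beam == "parallel":
        spacing = geom.bin_len
        q = filter_sinogram(data, spacing, filter_name)
    else:
        dso, dsd = geom.dso, geom.dsd
        s_iso = geom.bin_centers * dso / dsd
        spacing = geom.bin_len * dso / dsd
        cosw = dso / np.sqrt(dso ** 2 + s_iso ** 2)
        q = filter_sinogram(data * cosw[None, :], spacing, filter_name)
    B = _fbp_backprojector(geom)
    img = (B @ q.ravel()).reshape(geom.n_voxels, geom.n_voxels)
    return ImageGrid(img, geom.voxel_len, "mu")


def fbp_operator(geom: ScanGeometry, filter_name: Optional[str] = None):
    """(apply, apply_transpose) pair for FBP as a linear map on sinograms.

    Used as the optional filtered variant of the differentiable
    back-projection layer.  The ramp filter is a symmetric circular
    convolution per view, so its transpose is itself; the transpose of the
    pixel-driven back-projector is applied explicitly.
    """
    filter_name = filter_name or geom.filter_name
    B = _fbp_backprojector(geom)
    if geom.beam == "parallel":
        spacing = geom.bin_len
        cosw = None
    else:
        dso, dsd = geom.dso, geom.dsd
        s_iso = geom.bin_centers * dso / dsd
        spacing = geom.bin_len * dso / dsd
        cosw = dso / np.sqrt(dso ** 2 + s_iso ** 2)

    def _filt(x):
        return filter_sinogram(x, spacing, filter_name)

    def apply(sino_data: np.ndarray) -> np.ndarray:
        d = sino_data if cosw is None else sino_data * cosw[None, :]
        q = _filt(d)
        return (B @ q.ravel()).reshape(geom.n_voxels, geom.n_voxels)

    def apply_t(img_data: np.ndarray) -> np.ndarray:
        g = (B.T @ img_data.ravel()).reshape(geom.n_views, geom.n_bins)
        g = _filt(g)  # symmetric filter
        return g if cosw is None else g * cosw[None, :]

    return apply, apply_t


def bp_operator(geom: ScanGeometry):
    """(apply, apply_transpose) pair for the plain adjoint back-projection."""
    A = system_matrix(geom)
    scale = math.pi / (geom.n_views * geom.voxel_len)

    def apply(sino_data: np.ndarray) -> np.ndarray:
        return (A.T @ sino_data.ravel()).reshape(
            geom.n_voxels, geom.n_voxels) * scale

    def apply_t(img_data: np.ndarray) -> np.ndarray:
        return (A @ img_data.ravel()).reshape(
            geom.n_views, geom.n_bins) * scale

    return apply, apply_t
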