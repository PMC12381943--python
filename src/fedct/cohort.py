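"""Synthetic multi-client phantom cohorts and heterogeneity statistics.

Clinical multi-vendor data is replaced by procedurally generated, region-coded
phantoms: an elliptical body containing random internal structures whose
Hounsfield statistics mimic the coded anatomical region (1 = brain-like,
2 = abdomen-like, 3 = chest-like, 4 = physical-phantom-like).  From each
phantom an ideal sinogram is simulated and degraded per the client's dose
protocol; the server's metadata pool draws random protocols from a diverse
family.

Cohort heterogeneity is quantified exactly as one would for real data: KL
divergence between pooled intensity histograms and distances between mean
gray-level co-occurrence (GLCM) texture features, with Wilcoxon rank-sum
tests on the per-image feature values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import ranksums
from skimage.feature import graycomatrix, graycoprops

from .geometry import (ImageGrid, ScanGeometry, Sinogram, forward_project,
                       hu_to_mu, fbp_reconstruct)
from .lowdose import DoseProtocol, apply_protocol
from .prompt import ConditionVector, encode_condition

REGION_NAMES = {1: "brain", 2: "abdomen", 3: "chest", 4: "phantom"}

# per-region structure value intervals (HU); background is -1000 (air)
REGION_HU_RANGES = {
    1: {"body": (20, 60), "rim": (800, 1200), "structs": (-20, 100)},
    2: {"body": (30, 70), "rim": None, "structs": (-900, 1100)},
    3: {"body": (20, 60), "rim": None, "structs": (-880, 800)},
    4: {"body": (0, 0), "rim": None, "structs": (-800, 800)},
}

# fixed palette for the piecewise-constant physical-phantom region
PHANTOM_PALETTE = (-800.0, -400.0, -100.0, 100.0, 400.0, 800.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one procedural phantom."""

    region_code: int
    n_voxels: int
    voxel_len: float
    n_structures: tuple = (3, 7)  # inclusive range
    body_radius_frac: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.region_code <= 4:
            raise ValueError("region_code must be 1..4")
        if not 0 < self.body_radius_frac <= 1.0:
            raise ValueError("body_radius_frac must lie in (0, 1]")


def _ellipse_mask(n: int, cx, cy, a, b, angle=0.0) -> np.ndarray:
    """Boolean ellipse mask in normalised [-1, 1] coordinates."""
    c = (np.arange(n) + 0.5 - n / 2.0) / (n / 2.0)
    X, Y = np.meshgrid(c, c)
    ca, sa = math.cos(angle), math.sin(angle)
    xr = (X - cx) * ca + (Y - cy) * sa
    yr = -(X - cx) * sa + (Y - cy) * ca
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Region-coded piecewise-constant phantom in HU; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_voxels
    img = np.full((n, n), -1000.0)  # air
    ranges = REGION_HU_RANGES[spec.region_code]
    R = spec.body_radius_frac

    if spec.region_code == 1:  # brain: round body with a high-HU rim
        a = b = R * rng.uniform(0.9, 1.0)
        rim_val = rng.uniform(*ranges["rim"])
        body_val = rng.uniform(*ranges["body"])
        rim = _ellipse_mask(n, 0, 0, a, b)
        inner = _ellipse_mask(n, 0, 0, 0.88 * a, 0.88 * b)
        img[rim] = rim_val
        img[inner] = body_val
        body_a, body_b, body_angle = 0.88 * a, 0.88 * b, 0.0
    else:
        body_a = R * rng.uniform(0.85, 1.0)
        body_b = body_a * rng.uniform(0.6, 0.9)
        body_angle = 0.0
        body_val = float(rng.uniform(*ranges["body"]))
        img[_ellipse_mask(n, 0, 0, body_a, body_b, body_angle)] = body_val
        body_a *= 1.0
        body_b *= 1.0

    lo, hi = spec.n_structures
    k = int(rng.integers(lo, hi + 1))
    if spec.region_code == 4:
        k = min(k, 6)  # body + background + <=6 inserts stays within 8 values
        values = rng.choice(PHANTOM_PALETTE, size=k, replace=False)
    elif spec.region_code == 3:
        # two lung-like low-attenuation regions first
        for sign in (-1, 1):
            la = body_a * rng.uniform(0.30, 0.38)
            lb = body_b * rng.uniform(0.5, 0.65)
            img[_ellipse_mask(n, sign * 0.42 * body_a, 0.0, la, lb)] = \
                rng.uniform(-880, -700)
        values = rng.uniform(-100, 800, size=k)
    else:
        values = rng.uniform(*ranges["structs"], size=k)

    for val in np.atleast_1d(values):
        # structure contained in the body: centre + radius stays inside
        r_s = rng.uniform(0.05, 0.18)
        margin = 1.0 - r_s / min(body_a, body_b) - 0.05
        rho = math.sqrt(rng.uniform(0, max(margin, 0.0) ** 2))
        phi = rng.uniform(0, 2 * math.pi)
        cx = rho * body_a * math.cos(phi)
        cy = rho * body_b * math.sin(phi)
        aa = r_s * rng.uniform(0.6, 1.0)
        bb = r_s * rng.uniform(0.6, 1.0)
        if spec.region_code == 4:
            aa = bb = r_s  # discs
        mask = _ellipse_mask(n, cx, cy, aa, bb, rng.uniform(0, math.pi))
        img[mask] = float(val)

    return ImageGrid(np.clip(img, -1000.0, 3000.0), spec.voxel_len, "HU")


# ---------------------------------------------------------------------------
# client datasets and the server metadata pool
# ---------------------------------------------------------------------------

@dataclass
class DataItem:
    sino: Sinogram                    # degraded measurement
    reference: Optional[ImageGrid]    # clean mu image (None when unpaired)
    clean_sino: Optional[Sinogram] = None
    condition: Optional[ConditionVector] = None


@dataclass
class ClientDataset:
    client_id: str
    geometry: ScanGeometry            # full acquisition geometry
    degraded_geometry: ScanGeometry   # geometry of the stored sinograms
    protocol: DoseProtocol
    items: List[DataItem]
    splits: dict                      # name -> list of indices
    condition: ConditionVector = None

    def subset(self, name: str) -> List[DataItem]:
        return [self.items[i] for i in self.splits[name]]

    def references(self, name: str = None) -> List[ImageGrid]:
        idx = range(len(self.items)) if name is None else self.splits[name]
        return [self.items[i].reference for i in idx
                if self.items[i].reference is not None]


def split_indices(n: int, seed: int,
                  fractions=(0.85, 0.05, 0.10)) -> dict:
    """Random 85/5/10 train/val/test split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = max(int(round(fractions[1] * n)), 1)
    n_test = n - n_train - n_val
    if n_test < 1 or n_train < 1:
        raise ValueError("dataset too small for an 85/5/10 split")
    return {
        "train": sorted(perm[:n_train].tolist()),
        "val": sorted(perm[n_train:n_train + n_val].tolist()),
        "test": sorted(perm[n_train + n_val:].tolist()),
    }


def build_client_dataset(client_id: str, geometry: ScanGeometry,
                         protocol: DoseProtocol, n_images: int,
                         seed: int, body_radius_frac: float = 0.85,
                         n_structures=(3, 7)) -> ClientDataset:
    """Simulate one client: phantoms -> ideal sinograms -> degraded inputs."""
    if n_images < 20:
        raise ValueError("n_images must be >= 20 for an 85/5/10 split")
    rng = np.random.default_rng(seed)
    cond = encode_condition(geometry, protocol)
    items: List[DataItem] = []
    degraded_geom = None
    for i in range(n_images):
        spec = PhantomSpec(protocol.region_code, geometry.n_voxels,
                           geometry.voxel_len,
                           n_structures=n_structures,
                           body_radius_frac=body_radius_frac,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        mu_img = generate_phantom(spec).to_mu()
        clean = forward_project(mu_img, geometry)
        degraded = apply_protocol(clean, protocol,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        degraded_geom = degraded.geometry
        items.append(DataItem(degraded, mu_img, clean, cond))
    splits = split_indices(n_images, seed + 1)
    if not protocol.paired:
        for i in splits["train"]:
            items[i] = DataItem(items[i].sino, None, items[i].clean_sino,
                                items[i].condition)
    return ClientDataset(client_id, geometry, degraded_geom, protocol,
                         items, splits, cond)


@dataclass
class MetadataPool:
    """Server-side paired (low-dose image, normal-dose image) collection."""

    pairs: List[dict]  # {'low': ImageGrid, 'ref': ImageGrid, 'condition': ...}

    def __len__(self):
        return len(self.pairs)


def default_protocol_family(situation: int = 2) -> List[DoseProtocol]:
    """Protocol families mirroring the three study situations:
    1 — low-mAs only; 2 — mixed low-mAs / sparse-view / limited-angle;
    3 — low-mAs pool used alongside unpaired clients."""
    low_mas = [DoseProtocol("low_mAs", intensity_I0=i0, region_code=r)
               for i0 in (5e4, 1e5, 2e5, 3e5) for r in (1, 2, 3, 4)]
    if situation in (1, 3):
        return low_mas
    mixed = list(low_mas)
    mixed += [DoseProtocol("sparse_view", views_kept=v, region_code=r)
              for v in (48, 72, 96) for r in (1, 2, 3)]
    mixed += [DoseProtocol("limited_angle", angular_span=s, region_code=r)
              for s in (2 * math.pi / 3, math.pi / 2) for r in (1, 2, 3)]
    return mixed


def build_metadata_pool(n_pairs: int, protocol_family: Sequence[DoseProtocol],
                        geometry: ScanGeometry, seed: int) -> MetadataPool:
    """Each pair: (FBP of a degraded sinogram, clean reference image)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not protocol_family:
        raise ValueError("protocol family is empty")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        proto = protocol_family[int(rng.integers(len(protocol_family)))]
        spec = PhantomSpec(proto.region_code, geometry.n_voxels,
                           geometry.voxel_len,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        mu_img = generate_phantom(spec).to_mu()
        clean = forward_project(mu_img, geometry)
        degraded = apply_protocol(clean, proto,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        low = fbp_reconstruct(degraded, degraded.geometry)
        pairs.append({
            "low": low,
            "ref": mu_img,
            "condition": encode_condition(geometry, proto),
            "protocol": proto,
        })
    return MetadataPool(pairs)


# ---------------------------------------------------------------------------
# heterogeneity statistics
# ---------------------------------------------------------------------------

HIST_WINDOW = (-1000.0, 2000.0)
HIST_BINS = 256
HIST_EPS = 1e-10


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = HIST_EPS) -> float:
    """KL(p||q) in nats with additive smoothing; asymmetric by definition."""
    p = np.asarray(p, dtype=np.float64) + eps
    q = np.asarray(q, dtype=np.float64) + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def _pooled_histogram(images: Sequence[ImageGrid], n_bins: int,
                      window) -> np.ndarray:
    vals = np.concatenate([img.to_hu().data.ravel() for img in images])
    hist, _ = np.histogram(vals, bins=n_bins, range=window)
    if hist.sum() == 0:
        raise ValueError("no pixel values fall inside the histogram window")
    return hist.astype(np.float64)


def kl_histogram_divergence(a: Sequence[ImageGrid], b: Sequence[ImageGrid],
                            n_bins: int = HIST_BINS,
                            window=HIST_WINDOW) -> float:
    """KL(Pa||Pb) of pooled intensity histograms over a fixed HU window."""
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each image set needs at least one image")
    return kl_divergence(_pooled_histogram(a, n_bins, window),
                         _pooled_histogram(b, n_bins, window))


GLCM_LEVELS = 32
GLCM_FEATURES = ("contrast", "homogeneity", "energy", "correlation")


def quantize_image(img: ImageGrid, levels: int = GLCM_LEVELS,
                   window=HIST_WINDOW) -> np.ndarray:
    hu = img.to_hu().data
    scaled = (hu - window[0]) / (window[1] - window[0])
    return np.clip((scaled * levels).astype(np.int32), 0, levels - 1)


def glcm_features(img_q: np.ndarray, levels: int = GLCM_LEVELS) -> dict:
    """Mean GLCM contrast/homogeneity/energy/correlation at distance 1,
    angles 0 and 90 degrees."""
    glcm = graycomatrix(img_q.astype(np.uint8), distances=[1],
                        angles=[0.0, math.pi / 2], levels=levels,
                        symmetric=False, normed=True)
    return {f: float(np.mean(graycoprops(glcm, f))) for f in GLCM_FEATURES}


def glcm_feature_distance(a: Sequence[ImageGrid], b: Sequence[ImageGrid],
                          levels: int = GLCM_LEVELS):
    """Euclidean distance between per-set mean GLCM feature vectors.

    Returns ``(distance, feats_a, feats_b, pvalues)`` where the feature
    tables are per-image dicts and ``pvalues`` holds Wilcoxon rank-sum
    p-values per feature.  The correlation feature is dropped (with a
    warning) when every image in both sets is constant.
    """
    qa = [quantize_image(im, levels) for im in a]
    qb = [quantize_image(im, levels) for im in b]
    features = list(GLCM_FEATURES)
    if all(np.ptp(q) == 0 for q in qa + qb):
        warnings.warn("correlation undefined for constant images; dropped")
        features.remove("correlation")
    fa = [glcm_features(q, levels) for q in qa]
    fb = [glcm_features(q, levels) for q in qb]
    va = np.array([[f[k] for k in features] for f in fa])
    vb = np.array([[f[k] for k in features] for f in fb])
    distance = float(np.linalg.norm(va.mean(axis=0) - vb.mean(axis=0)))
    pvalues = {}
    for j, k in enumerate(features):
        if len(va) > 1 and len(vb) > 1:
            pvalues[k] = float(ranksums(va[:, j], vb[:, j]).pvalue)
    return distance, fa, fb, pvalues
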