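"""Synthetic cohort generation and heterogeneity statistics."""

import math

import numpy as np
import pytest

from fedct.cohort import (PHANTOM_PALETTE, PhantomSpec, build_client_dataset,
                          build_metadata_pool, default_protocol_family,
                          generate_phantom, glcm_feature_distance,
                          glcm_features, kl_divergence,
                          kl_histogram_divergence, quantize_image,
                          split_indices)
from fedct.geometry import ImageGrid, ScanGeometry
from fedct.lowdose import DoseProtocol


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def test_phantom_deterministic_and_bounded():
    spec = PhantomSpec(region_code=2, n_voxels=64, voxel_len=3.0, seed=5)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    np.testing.assert_array_equal(a.data, b.data)
    assert a.value_unit == "HU"
    assert a.data.min() >= -1000.0 and a.data.max() <= 3000.0
    # background is air
    assert a.data[0, 0] == -1000.0


def test_phantom_region4_palette():
    spec = PhantomSpec(region_code=4, n_voxels=64, voxel_len=3.0, seed=1)
    img = generate_phantom(spec)
    vals = set(np.unique(img.data))
    allowed = set(PHANTOM_PALETTE) | {-1000.0}
    # background + body + <=6 palette inserts, all piecewise constant
    assert len(vals) <= 8
    assert len(vals - allowed) <= 1  # only the body value is free


def test_phantom_seeds_differ():
    a = generate_phantom(PhantomSpec(1, 64, 3.0, seed=0))
    b = generate_phantom(PhantomSpec(1, 64, 3.0, seed=1))
    assert not np.array_equal(a.data, b.data)


def test_phantom_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(region_code=0, n_voxels=64, voxel_len=3.0)
    with pytest.raises(ValueError):
        PhantomSpec(region_code=1, n_voxels=64, voxel_len=3.0,
                    body_radius_frac=0.0)


# ---------------------------------------------------------------------------
# datasets and metadata pool
# ---------------------------------------------------------------------------

def test_split_indices_counts():
    s = split_indices(20, seed=0)
    assert len(s["train"]) == 17 and len(s["val"]) == 1 and len(s["test"]) == 2
    assert sorted(s["train"] + s["val"] + s["test"]) == list(range(20))
    with pytest.raises(ValueError):
        split_indices(3, seed=0)


def test_build_client_dataset_paired_and_unpaired():
    geom = ScanGeometry(32, 3.0, 48, 47, 3.0)
    proto = DoseProtocol("low_mAs", intensity_I0=2e5, region_code=2)
    ds = build_client_dataset("c1", geom, proto, 20, seed=3)
    assert len(ds.items) == 20
    assert all(it.reference is not None for it in ds.items)
    assert ds.degraded_geometry == geom

    unp = DoseProtocol("low_mAs", intensity_I0=2e5, region_code=2,
                       paired=False)
    ds_u = build_client_dataset("c2", geom, unp, 20, seed=3)
    assert all(ds_u.items[i].reference is None for i in ds_u.splits["train"])
    assert all(ds_u.items[i].reference is not None
               for i in ds_u.splits["test"])


def test_build_client_dataset_sparse_view_geometry():
    geom = ScanGeometry(32, 3.0, 96, 47, 3.0)
    proto = DoseProtocol("sparse_view", views_kept=48, region_code=3)
    ds = build_client_dataset("c", geom, proto, 20, seed=0)
    assert ds.degraded_geometry.n_views == 48
    assert ds.items[0].sino.data.shape == (48, 47)


def test_metadata_pool_build():
    geom = ScanGeometry(32, 3.0, 48, 47, 3.0)
    pool = build_metadata_pool(6, default_protocol_family(2), geom, seed=1)
    assert len(pool) == 6
    for pair in pool.pairs:
        assert pair["low"].data.shape == (32, 32)
        assert pair["ref"].value_unit == "mu"
    with pytest.raises(ValueError):
        build_metadata_pool(0, default_protocol_family(1), geom, seed=0)


def test_default_protocol_families():
    fam1 = default_protocol_family(1)
    fam2 = default_protocol_family(2)
    assert all(p.condition == "low_mAs" for p in fam1)
    conds = {p.condition for p in fam2}
    assert conds == {"low_mAs", "sparse_view", "limited_angle"}


# ---------------------------------------------------------------------------
# heterogeneity statistics
# ---------------------------------------------------------------------------

def test_kl_two_bin_hand_case():
    """KL([.5,.5] || [.9,.1]) = 0.5*ln(25/9) = 0.5108 nats."""
    val = kl_divergence(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
    assert val == pytest.approx(0.5 * math.log(25.0 / 9.0), abs=1e-4)
    assert val == pytest.approx(0.5108, abs=1e-4)


def test_kl_identical_sets_is_zero():
    imgs = [generate_phantom(PhantomSpec(2, 32, 3.0, seed=s))
            for s in range(3)]
    assert kl_histogram_divergence(imgs, imgs) == pytest.approx(0.0,
                                                                abs=1e-12)


def test_kl_heterogeneous_sets_positive_and_asymmetric():
    a = [generate_phantom(PhantomSpec(1, 32, 3.0, seed=s)) for s in range(4)]
    b = [generate_phantom(PhantomSpec(3, 32, 3.0, seed=s)) for s in range(4)]
    kab = kl_histogram_divergence(a, b)
    kba = kl_histogram_divergence(b, a)
    assert kab > 0.0 and kba > 0.0
    assert kab != pytest.approx(kba, rel=1e-6)


def test_glcm_constant_and_checkerboard():
    const = np.zeros((8, 8), dtype=np.int32)
    f = glcm_features(const, levels=2)
    assert f["contrast"] == pytest.approx(0.0, abs=1e-12)
    assert f["energy"] == pytest.approx(1.0, abs=1e-12)

    checker = np.indices((8, 8)).sum(axis=0) % 2
    fc = glcm_features(checker.astype(np.int32), levels=2)
    # every distance-1 pair along 0 and 90 degrees is (0,1) or (1,0):
    # contrast = sum P(i,j)(i-j)^2 = 1, homogeneity = 1/2, energy = sqrt(1/2)
    assert fc["contrast"] == pytest.approx(1.0, abs=1e-12)
    assert fc["homogeneity"] == pytest.approx(0.5, abs=1e-12)
    assert fc["energy"] == pytest.approx(math.sqrt(0.5), abs=1e-12)


def test_glcm_feature_distance_constant_images_drops_correlation():
    a = [ImageGrid(np.zeros((16, 16)), 3.0, "HU") for _ in range(2)]
    b = [ImageGrid(np.full((16, 16), 500.0), 3.0, "HU") for _ in range(2)]
    with pytest.warns(UserWarning):
        dist, fa, fb, pv = glcm_feature_distance(a, b)
    assert dist == pytest.approx(0.0, abs=1e-12)  # both constant textures
    assert "correlation" not in pv


def test_glcm_feature_distance_phantom_sets():
    a = [generate_phantom(PhantomSpec(1, 32, 3.0, seed=s)) for s in range(3)]
    b = [generate_phantom(PhantomSpec(3, 32, 3.0, seed=s)) for s in range(3)]
    dist, fa, fb, pv = glcm_feature_distance(a, b)
    assert dist > 0.0
    assert set(pv) == {"contrast", "homogeneity", "energy", "correlation"}
    assert all(0.0 <= p <= 1.0 for p in pv.values())


def test_quantize_image_range():
    img = ImageGrid(np.linspace(-1500, 2500, 256).reshape(16, 16), 3.0, "HU")
    q = quantize_image(img, levels=32)
    assert q.min() == 0 and q.max() == 31
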