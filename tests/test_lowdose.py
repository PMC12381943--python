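"""Low-dose degradation: noise statistics, view subsetting, configs."""

import math

import numpy as np
import pytest

from fedct.geometry import ScanGeometry, Sinogram, uniform_angles
from fedct.lowdose import (DoseProtocol, apply_protocol, degraded_geometry,
                           simulate_low_mAs, sparse_view_indices,
                           subsample_views, truncate_angles)


def _flat_sino(n_views, n_bins, value=1.0, **geom_kw):
    geom = ScanGeometry(max(n_bins, 16), 3.0, n_views, n_bins, 3.0, **geom_kw)
    return Sinogram(np.full((n_views, n_bins), value), geom)


# ---------------------------------------------------------------------------
# protocol dataclass
# ---------------------------------------------------------------------------

def test_protocol_validation():
    with pytest.raises(ValueError):
        DoseProtocol("low_mAs")                    # missing intensity
    with pytest.raises(ValueError):
        DoseProtocol("sparse_view", views_kept=0)
    with pytest.raises(ValueError):
        DoseProtocol("limited_angle")              # missing span
    with pytest.raises(ValueError):
        DoseProtocol("low_mAs", intensity_I0=1e5, region_code=9)
    with pytest.raises(ValueError):
        DoseProtocol("half_dose")


def test_protocol_config_roundtrip():
    protos = [
        DoseProtocol("low_mAs", intensity_I0=2e5, region_code=2),
        DoseProtocol("sparse_view", views_kept=96, region_code=3,
                     paired=False),
        DoseProtocol("limited_angle", angular_span=2 * math.pi / 3,
                     angular_start=0.5, region_code=1),
        DoseProtocol("none"),
    ]
    for p in protos:
        assert DoseProtocol.from_config(p.to_config()) == p


# ---------------------------------------------------------------------------
# low-mAs Poisson model
# ---------------------------------------------------------------------------

def test_low_mAs_variance_matches_delta_method():
    """var(ln(I0/count)) ~= exp(p)/I0 within 10 percent at I0 = 1e4."""
    p0, I0 = 1.0, 1.0e4
    sino = _flat_sino(100, 101, value=p0)  # 10100 rays > 1e4
    noisy = simulate_low_mAs(sino, I0, seed=11)
    emp = float(np.var(noisy.data))
    pred = math.exp(p0) / I0
    assert abs(emp - pred) / pred < 0.10


def test_low_mAs_deterministic_and_floor():
    sino = _flat_sino(10, 17, value=2.0)
    a = simulate_low_mAs(sino, 1e4, seed=3)
    b = simulate_low_mAs(sino, 1e4, seed=3)
    c = simulate_low_mAs(sino, 1e4, seed=4)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
    # the one-photon floor bounds the noisy line integral by ln(I0)
    hot = _flat_sino(10, 17, value=50.0)   # essentially zero transmission
    out = simulate_low_mAs(hot, 1e4, seed=0)
    assert np.all(out.data <= math.log(1e4) + 1e-12)


def test_low_mAs_rejects_bad_input():
    sino = _flat_sino(4, 17, value=1.0)
    with pytest.raises(ValueError):
        simulate_low_mAs(sino, 0.0, seed=0)
    bad = Sinogram(np.full((4, 17), -1.0), sino.geometry)
    with pytest.raises(ValueError):
        simulate_low_mAs(bad, 1e4, seed=0)


# ---------------------------------------------------------------------------
# sparse-view and limited-angle
# ---------------------------------------------------------------------------

def test_sparse_view_indices_rule():
    np.testing.assert_array_equal(sparse_view_indices(192, 96),
                                  np.arange(0, 192, 2))
    idx = sparse_view_indices(180, 48)
    assert len(idx) == 48 and idx[0] == 0 and idx[-1] < 180
    assert len(np.unique(idx)) == 48


def test_subsample_views_geometry():
    sino = _flat_sino(192, 17)
    sub = subsample_views(sino, 96)
    assert sub.data.shape == (96, 17)
    assert sub.geometry.n_views == 96
    np.testing.assert_allclose(sub.geometry.angles,
                               sino.geometry.angles[::2])
    with pytest.raises(ValueError):
        subsample_views(sino, 400)


def test_truncate_angles_view_count():
    """512 views over 2*pi restricted to span 2*pi/3 keeps 171 views."""
    angles = uniform_angles(512, 2 * math.pi)
    geom = ScanGeometry(16, 3.0, 512, 17, 3.0, view_angles=tuple(angles))
    sino = Sinogram(np.zeros((512, 17)), geom)
    out = truncate_angles(sino, 2 * math.pi / 3)
    assert out.geometry.n_views == 171
    assert out.geometry.angles[-1] < 2 * math.pi / 3


def test_truncate_angles_start_offset():
    sino = _flat_sino(180, 17)  # parallel default span pi
    out = truncate_angles(sino, math.pi / 2, start=math.pi / 4)
    assert np.all(out.geometry.angles >= math.pi / 4 - 1e-12)
    assert np.all(out.geometry.angles < 3 * math.pi / 4)


def test_apply_protocol_dispatch_and_degraded_geometry():
    sino = _flat_sino(192, 17, value=1.0)
    for proto in (DoseProtocol("low_mAs", intensity_I0=1e5),
                  DoseProtocol("sparse_view", views_kept=96),
                  DoseProtocol("limited_angle", angular_span=math.pi / 2),
                  DoseProtocol("none")):
        out = apply_protocol(sino, proto, seed=0)
        geom = degraded_geometry(sino.geometry, proto)
        assert out.geometry == geom
        assert out.data.shape == (geom.n_views, geom.n_bins)
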