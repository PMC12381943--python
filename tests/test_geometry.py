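"""Projector, filter and FBP correctness against analytic oracles."""

import math

import numpy as np
import pytest

from fedct.geometry import (FILTERS, MU_WATER, GeometryError, ImageGrid,
                            ScanGeometry, Sinogram, back_project,
                            bp_operator, fbp_operator, fbp_reconstruct,
                            filter_sinogram, forward_project, hu_to_mu,
                            mu_to_hu, ramp_filter_response, system_matrix,
                            uniform_angles)

from conftest import make_disk


# ---------------------------------------------------------------------------
# units and construction
# ---------------------------------------------------------------------------

def test_hu_mu_roundtrip():
    hu = np.array([-1000.0, 0.0, 1000.0])
    mu = hu_to_mu(hu)
    assert mu[1] == pytest.approx(MU_WATER)
    assert mu[0] == pytest.approx(0.0)
    np.testing.assert_allclose(mu_to_hu(mu), hu, atol=1e-12)


def test_geometry_validation():
    with pytest.raises(GeometryError):
        ScanGeometry(0, 3.0, 10, 11, 3.0)
    with pytest.raises(GeometryError):
        ScanGeometry(16, 3.0, 10, 11, 3.0, filter_name="boxcar")
    with pytest.raises(GeometryError):
        ScanGeometry(16, 3.0, 10, 11, 3.0, beam="fanflat")  # missing dsd/dso
    with pytest.raises(GeometryError):
        # dso must exceed half the field of view
        ScanGeometry(64, 3.0, 10, 11, 3.0, beam="fanflat", dsd=100.0, dso=50.0)


def test_geometry_config_roundtrip(small_geom):
    geom2 = ScanGeometry.from_config(small_geom.to_config())
    assert geom2 == small_geom
    fan = ScanGeometry(32, 3.0, 24, 63, 3.0, beam="fanflat",
                       dsd=1000.0, dso=500.0)
    assert ScanGeometry.from_config(fan.to_config()) == fan
    assert fan.fingerprint() != small_geom.fingerprint()


def test_sinogram_shape_guard(small_geom):
    with pytest.raises(GeometryError):
        Sinogram(np.zeros((3, 3)), small_geom)


def test_uniform_angles():
    a = uniform_angles(4, math.pi)
    np.testing.assert_allclose(a, [0, math.pi / 4, math.pi / 2,
                                   3 * math.pi / 4])


# ---------------------------------------------------------------------------
# projector: adjointness and analytic chord lengths
# ---------------------------------------------------------------------------

def test_projector_adjoint_small_instances():
    """<A x, y> == <x, A^T y> on 20 random geometries, 16-64 px."""
    rng = np.random.default_rng(7)
    for trial in range(20):
        n = int(rng.integers(16, 65))
        nb = int(rng.integers(n - 4, n + 12)) | 1
        nv = int(rng.integers(8, 40))
        beam = "fanflat" if trial % 3 == 0 else "parallel"
        kw = {}
        if beam == "fanflat":
            kw = {"dsd": 4.0 * n * 3.0, "dso": 2.0 * n * 3.0}
        geom = ScanGeometry(n, 3.0, nv, nb, 3.0, beam=beam, **kw)
        A = system_matrix(geom)
        x = rng.standard_normal(A.shape[1])
        y = rng.standard_normal(A.shape[0])
        lhs = float((A @ x) @ y)
        rhs = float(x @ (A.T @ y))
        assert lhs == pytest.approx(rhs, rel=1e-4)


def test_back_project_is_scaled_adjoint(small_geom):
    rng = np.random.default_rng(1)
    sino = Sinogram(rng.random((small_geom.n_views, small_geom.n_bins)),
                    small_geom)
    img = back_project(sino, small_geom)
    A = system_matrix(small_geom)
    scale = math.pi / (small_geom.n_views * small_geom.voxel_len)
    expected = (A.T @ sino.data.ravel()).reshape(32, 32) * scale
    np.testing.assert_allclose(img.data, expected, rtol=1e-10)


def test_disk_chord_lengths():
    """Parallel projection of a uniform disk equals 2*mu*sqrt(r^2 - s^2)."""
    geom = ScanGeometry(64, 3.0, 60, 95, 3.0)
    mu = 0.02
    img = make_disk(64, 3.0, radius_frac=0.35, value=mu)
    sino = forward_project(img, geom)
    r = 0.35 * 64 * 3.0
    s = geom.bin_centers
    expected = np.where(np.abs(s) < r, 2.0 * mu * np.sqrt(
        np.maximum(r ** 2 - s ** 2, 0.0)), 0.0)
    # compare where the chord is long enough that pixelisation is small
    mask = np.abs(s) < 0.8 * r
    err = np.linalg.norm(sino.data[0, mask] - expected[mask])
    ref = np.linalg.norm(expected[mask])
    assert err / ref < 0.01


def test_forward_project_linearity(small_geom):
    rng = np.random.default_rng(3)
    a = ImageGrid(rng.random((32, 32)), 3.0, "mu")
    b = ImageGrid(rng.random((32, 32)), 3.0, "mu")
    combo = ImageGrid(2.0 * a.data - 0.5 * b.data, 3.0, "mu")
    lhs = forward_project(combo, small_geom).data
    rhs = (2.0 * forward_project(a, small_geom).data
           - 0.5 * forward_project(b, small_geom).data)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


# ---------------------------------------------------------------------------
# ramp filter and FBP
# ---------------------------------------------------------------------------

def test_ramp_filter_kernel_values():
    """The unapodised frequency response is the transform of the
    band-limited ramp kernel: h[0] = 1/(4 ds^2), h[even] = 0,
    h[odd] = -1/(pi k ds)^2."""
    ds, n = 2.0, 32
    H = ramp_filter_response(n, ds, "ram-lak")
    h = np.real(np.fft.ifft(H))
    assert h[0] == pytest.approx(1.0 / (4.0 * ds ** 2), rel=1e-12)
    assert h[2] == pytest.approx(0.0, abs=1e-15)
    assert h[1] == pytest.approx(-1.0 / (math.pi * 1 * ds) ** 2, rel=1e-12)
    assert h[3] == pytest.approx(-1.0 / (math.pi * 3 * ds) ** 2, rel=1e-12)
    assert h[1] == pytest.approx(h[-1], rel=1e-12)  # symmetric kernel
    # frequency response is real and nonnegative for the plain ramp
    assert np.all(H >= -1e-12)


@pytest.mark.parametrize("name", FILTERS)
def test_filter_sinogram_runs(name):
    rng = np.random.default_rng(0)
    data = rng.random((4, 33))
    out = filter_sinogram(data, 3.0, name)
    assert out.shape == data.shape
    assert np.all(np.isfinite(out))


def test_fbp_disk_interior_accuracy(medium_geom):
    """Noiseless FBP of a uniform disk: interior relative RMSE < 5 percent,
    decreasing monotonically as the view count doubles."""
    img = make_disk(64, 3.0, radius_frac=0.35, value=0.02)
    c = (np.arange(64) + 0.5 - 32.0) * 3.0
    X, Y = np.meshgrid(c, c)
    interior = X ** 2 + Y ** 2 <= (0.8 * 0.35 * 64 * 3.0) ** 2
    errs = []
    for nv in (45, 90, 180):
        geom = ScanGeometry(64, 3.0, nv, 95, 3.0)
        rec = fbp_reconstruct(forward_project(img, geom), geom)
        err = np.sqrt(np.mean((rec.data[interior] - 0.02) ** 2)) / 0.02
        errs.append(err)
    assert errs[-1] < 0.05
    assert errs[0] > errs[1] > errs[2]


def test_fbp_fan_beam_runs():
    geom = ScanGeometry(64, 3.0, 96, 127, 3.0, beam="fanflat",
                        dsd=1000.0, dso=500.0)
    img = make_disk(64, 3.0, value=0.02)
    rec = fbp_reconstruct(forward_project(img, geom), geom)
    c = (np.arange(64) + 0.5 - 32.0) * 3.0
    X, Y = np.meshgrid(c, c)
    interior = X ** 2 + Y ** 2 <= (0.8 * 0.35 * 64 * 3.0) ** 2
    err = np.sqrt(np.mean((rec.data[interior] - 0.02) ** 2)) / 0.02
    assert err < 0.05


def test_fbp_operator_adjoint(small_geom):
    """The differentiable FBP operator and its stated transpose satisfy the
    dot-product identity."""
    apply_fn, apply_t = fbp_operator(small_geom)
    rng = np.random.default_rng(5)
    s = rng.standard_normal((small_geom.n_views, small_geom.n_bins))
    v = rng.standard_normal((32, 32))
    lhs = float(np.sum(apply_fn(s) * v))
    rhs = float(np.sum(s * apply_t(v)))
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_bp_operator_adjoint(small_geom):
    apply_fn, apply_t = bp_operator(small_geom)
    rng = np.random.default_rng(6)
    s = rng.standard_normal((small_geom.n_views, small_geom.n_bins))
    v = rng.standard_normal((32, 32))
    assert float(np.sum(apply_fn(s) * v)) == pytest.approx(
        float(np.sum(s * apply_t(v))), rel=1e-8)
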