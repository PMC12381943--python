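"""Aggregation, privacy gate, weight divergence and a miniature federation."""

import numpy as np
import pytest

from fedct.federation import (MODES, FederationConfig, PrivacyViolation,
                              aggregate, run_federation, validate_upload,
                              weight_divergence)
from fedct.geometry import ScanGeometry
from fedct.lowdose import DoseProtocol
from fedct.cohort import build_client_dataset, build_metadata_pool, \
    default_protocol_family
from fedct.models import ModelConfig
from fedct.objectives import LossWeights, OptimizerSettings
from fedct.params import ParamSet


def _ps(vals, role="shared"):
    return ParamSet({k: np.asarray(v, dtype=np.float64)
                     for k, v in vals.items()}, role)


# ---------------------------------------------------------------------------
# aggregation hand case: 0.55*1 + 0.45*(0.5*2 + 0.5*4) = 1.90
# ---------------------------------------------------------------------------

def test_aggregate_hand_case():
    server = _ps({"w": [1.0]})
    clients = [_ps({"w": [2.0]}), _ps({"w": [4.0]})]
    out = aggregate(server, clients, omega_c=0.55, omega_k=[0.5, 0.5])
    assert out["w"][0] == pytest.approx(1.90, abs=1e-9)


def test_aggregate_edge_cases_and_validation():
    server = _ps({"w": [1.0]})
    clients = [_ps({"w": [3.0]})]
    assert aggregate(server, clients, 1.0, [1.0])["w"][0] == 1.0
    assert aggregate(server, clients, 0.0, [1.0])["w"][0] == 3.0
    with pytest.raises(ValueError):
        aggregate(server, clients, 1.5, [1.0])
    with pytest.raises(ValueError):
        aggregate(server, clients, 0.5, [0.7, 0.3])   # wrong count
    with pytest.raises(ValueError):
        aggregate(server, clients, 0.5, [0.9])        # does not sum to 1


def test_aggregate_convexity_envelope():
    rng = np.random.default_rng(0)
    for _ in range(10):
        vals = rng.standard_normal((3, 4))
        server = _ps({"w": vals[0]})
        clients = [_ps({"w": vals[1]}), _ps({"w": vals[2]})]
        wk = rng.dirichlet(np.ones(2))
        oc = rng.uniform(0, 1)
        out = aggregate(server, clients, oc, wk)["w"]
        assert np.all(out <= vals.max(axis=0) + 1e-12)
        assert np.all(out >= vals.min(axis=0) - 1e-12)


# ---------------------------------------------------------------------------
# weight divergence hand case: 0.3 + 0.3 = 0.6
# ---------------------------------------------------------------------------

def test_weight_divergence_hand_case():
    local = _ps({"a": [1.0, 0.0], "b": [0.0, 2.0]})
    fl = _ps({"a": [1.3, 0.0], "b": [0.0, 2.6]})
    assert weight_divergence(fl, local) == pytest.approx(0.6, abs=1e-9)
    assert weight_divergence(local, local) == 0.0


def test_weight_divergence_zero_norm_guard():
    local = _ps({"a": [0.0, 0.0]})
    fl = _ps({"a": [1.0, 0.0]})
    with pytest.raises(ValueError):
        weight_divergence(fl, local)


# ---------------------------------------------------------------------------
# privacy gate
# ---------------------------------------------------------------------------

def test_validate_upload_accepts_shared_and_prompt():
    upload = {"shared": _ps({"head.weight": np.ones(3)}, "shared"),
              "prompt": _ps({"units.0.fc1.weight": np.ones(3)}, "prompt")}
    validate_upload(upload)  # should not raise


def test_validate_upload_rejects_private_entries():
    upload = {"shared": _ps({"sino_net.head.weight": np.ones(3)}, "shared")}
    with pytest.raises(PrivacyViolation):
        validate_upload(upload)
    upload = {"shared": _ps({"image_net.out.weight": np.ones(3)}, "shared")}
    with pytest.raises(PrivacyViolation):
        validate_upload(upload)
    with pytest.raises(PrivacyViolation):
        validate_upload({"image_net": _ps({"w": np.ones(2)}, "image_net")})


# ---------------------------------------------------------------------------
# federation loop
# ---------------------------------------------------------------------------

def test_federation_config_validation():
    with pytest.raises(ValueError):
        FederationConfig(omega_c=1.2)
    with pytest.raises(ValueError):
        FederationConfig(mode="centralised")
    with pytest.raises(ValueError):
        FederationConfig(T=-1)
    assert set(MODES) == {"fedm2ct", "fedavg_baseline", "no_fmdl",
                          "no_cpml", "no_prompt"}


def _mini_setup(seed=0):
    geom = ScanGeometry(32, 3.0, 48, 47, 3.0)
    protos = [DoseProtocol("low_mAs", intensity_I0=2e5, region_code=2),
              DoseProtocol("sparse_view", views_kept=24, region_code=3)]
    datasets = [build_client_dataset(f"c{i+1}", geom, p, 20,
                                     seed=seed * 101 + i)
                for i, p in enumerate(protos)]
    pool = build_metadata_pool(4, default_protocol_family(2), geom,
                               seed=seed + 77)
    cfg = FederationConfig(
        T=1, iters_local=2, iters_shared=2, iters_meta=2, omega_c=0.55,
        seed=seed, batch_size=1,
        model=ModelConfig(sinogram_units=1, image_depth=2, shared_units=1,
                          base_channels=4, shared_channels=4, prompt_hidden=4,
                          groupnorm_groups=2, filtered_backprojection=True),
        weights=LossWeights(),
        opt_local=OptimizerSettings(learning_rate=1e-3),
        opt_meta=OptimizerSettings(learning_rate=1e-3))
    return cfg, datasets, pool


def test_run_federation_end_to_end():
    cfg, datasets, pool = _mini_setup()
    state = run_federation(cfg, datasets, pool)
    assert state.round == 1
    assert len(state.history) == 1
    rep = state.final_report
    assert set(rep["clients"]) == {"c1", "c2"}
    for r in rep["clients"].values():
        for metric in ("psnr", "ssim", "rmse"):
            assert np.isfinite(r["model"][metric])
            assert np.isfinite(r["fbp"][metric])
    assert rep["weight_divergence"] >= 0.0
    # after the broadcast every client holds the same shared parameters
    trunks = [c.shared.trunk_paramset() for c in state.clients]
    assert trunks[0].identical(trunks[1])
    assert trunks[0].allclose(state.server_trunk)


def test_run_federation_deterministic():
    cfg, datasets, pool = _mini_setup()
    a = run_federation(cfg, datasets, pool)
    cfg2, datasets2, pool2 = _mini_setup()
    b = run_federation(cfg2, datasets2, pool2)
    assert a.server_trunk.identical(b.server_trunk)
    assert a.final_report == b.final_report


def test_run_federation_zero_rounds_is_initial_broadcast():
    cfg, datasets, pool = _mini_setup()
    from dataclasses import replace
    state = run_federation(replace(cfg, T=0), datasets, pool)
    assert state.history == []
    trunks = [c.shared.trunk_paramset() for c in state.clients]
    assert trunks[0].identical(trunks[1])


def test_run_federation_requires_pool_when_meta_enabled():
    cfg, datasets, _ = _mini_setup()
    with pytest.raises(ValueError):
        run_federation(cfg, datasets, None)
    # the both-off baseline does not need a pool
    from dataclasses import replace
    state = run_federation(replace(cfg, mode="fedavg_baseline"),
                           datasets, None)
    assert state.round == 1
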