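"""Federated orchestration: local training, mutual sharing, metadata-anchored
aggregation, broadcast, and the weight-divergence diagnostic.

Per round each client alternates TS-iRadonMAP and shared-model updates on its
private data; the server trains the metamodel on its metadata pool; clients
upload only the shared-model (and prompt) parameters; the server forms

    theta_global = omega_c * theta_meta + (1 - omega_c) * sum_k omega_k * theta_k

and broadcasts it back.  The sinogram and image networks never leave the
client — every upload is validated and a stray private entry is a hard
failure.

Modes: ``fedm2ct`` (full), ``no_fmdl`` (no metamodel, omega_c = 0),
``no_cpml`` (no mutual learning or prompting, metadata anchor kept),
``no_prompt`` (full minus conditional prompting), and ``fedavg_baseline``
(plain parameter averaging with neither module — the both-off variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .autodiff import Tensor
from .cohort import ClientDataset, MetadataPool
from .evaluation import evaluate_pair_hu, psnr
from .geometry import ImageGrid, fbp_reconstruct
from .models import ModelConfig, SharedModel, TSIRadonMAP
from .objectives import (Adam, LossWeights, OptimizerSettings, meta_update,
                         mutual_round)
from .params import AggregationError, ParamSet, weighted_sum

MODES = ("fedm2ct", "fedavg_baseline", "no_fmdl", "no_cpml", "no_prompt")


class PrivacyViolation(RuntimeError):
    """A client upload contained private (sinogram/image network) entries."""


@dataclass(frozen=True)
class FederationConfig:
    T: int = 200
    iters_local: int = 100
    iters_shared: int = 100
    iters_meta: int = 200
    omega_c: float = 0.55
    omega_k: Optional[tuple] = None  # None -> uniform 1/K
    mode: str = "fedm2ct"
    seed: int = 0
    batch_size: int = 4
    model: ModelConfig = field(default_factory=ModelConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    opt_local: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(learning_rate=2e-5))
    opt_meta: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(learning_rate=1e-4))
    track_divergence: bool = True

    def __post_init__(self):
        if not 0.0 <= self.omega_c <= 1.0:
            raise ValueError("omega_c must lie in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.T < 0:
            raise ValueError("T must be nonnegative")


def _client_weights(cfg: FederationConfig, k: int) -> np.ndarray:
    if cfg.omega_k is None:
        return np.full(k, 1.0 / k)
    w = np.asarray(cfg.omega_k, dtype=np.float64)
    if len(w) != k or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("omega_k must be nonnegative and sum to 1")
    return w


class ClientState:
    """One client: private dual-domain model, shared model, optimisers."""

    def __init__(self, dataset: ClientDataset, cfg: FederationConfig,
                 model_cfg: ModelConfig, seed: int):
        self.dataset = dataset
        self.id = dataset.client_id
        self.weights = replace(
            cfg.weights,
            epsilon_k=cfg.weights.epsilon_k if dataset.protocol.paired
            else max(cfg.weights.epsilon_k, 0.1))
        self.mutual_enabled = cfg.mode not in ("no_cpml", "fedavg_baseline")
        self.ts = TSIRadonMAP(dataset.degraded_geometry, model_cfg, seed=seed)
        self.shared = SharedModel(model_cfg, seed=seed + 1)
        self.opt_local = Adam(self.ts.named_parameters(), cfg.opt_local)
        self.opt_shared = Adam(self.shared.named_parameters(), cfg.opt_local)
        self.shadow = None
        self.opt_shadow = None
        if cfg.track_divergence:
            self.shadow = SharedModel(model_cfg, seed=seed + 1)
            self.opt_shadow = Adam(self.shadow.named_parameters(),
                                   cfg.opt_local)
        self.batch_size = cfg.batch_size
        self._cond = dataset.condition
        self._train = dataset.subset("train")
        self._fbp_cache: Dict[int, dict] = {}

    def sample_batch(self, rng) -> list:
        idx = rng.integers(0, len(self._train), size=self.batch_size)
        return [self._train[i] for i in idx]

    def cond_tensor(self, batch: int) -> Tensor:
        return Tensor(np.repeat(self._cond.as_array()[None, :], batch, axis=0))

    # -- federation plumbing -------------------------------------------------
    def make_upload(self) -> Dict[str, ParamSet]:
        return {"shared": self.shared.trunk_paramset("shared"),
                "prompt": self.shared.prompt_paramset("prompt")}

    def receive(self, trunk: ParamSet, prompt: ParamSet):
        self.shared.load_trunk(trunk)
        self.shared.load_prompt(prompt)

    # -- evaluation ----------------------------------------------------------
    def reconstruct(self, item) -> ImageGrid:
        x = Tensor(item.sino.data[None, None].astype(np.float32))
        _, y = self.ts(x)
        return ImageGrid(np.asarray(y.data[0, 0], dtype=np.float64),
                         self.dataset.geometry.voxel_len, "mu")

    def evaluate(self, split: str = "test") -> dict:
        model_rows, fbp_rows = [], []
        for idx in self.dataset.splits[split]:
            item = self.dataset.items[idx]
            if item.reference is None:
                continue
            rec = self.reconstruct(item)
            model_rows.append(evaluate_pair_hu(rec, item.reference))
            if idx not in self._fbp_cache:
                fbp = fbp_reconstruct(item.sino, item.sino.geometry)
                self._fbp_cache[idx] = evaluate_pair_hu(fbp, item.reference)
            fbp_rows.append(self._fbp_cache[idx])
        agg = lambda rows, k: float(np.mean([r[k] for r in rows]))
        return {
            "model": {k: agg(model_rows, k) for k in ("psnr", "ssim", "rmse")},
            "fbp": {k: agg(fbp_rows, k) for k in ("psnr", "ssim", "rmse")},
        }


PRIVATE_PREFIXES = ("sino_net.", "image_net.")
ALLOWED_UPLOAD_ROLES = {"shared", "prompt"}


def validate_upload(upload: Dict[str, ParamSet]):
    """Hard privacy gate: only shared-model and prompt entries may leave."""
    for role, ps in upload.items():
        if role not in ALLOWED_UPLOAD_ROLES:
            raise PrivacyViolation(f"upload contains disallowed role {role!r}")
        for name in ps.keys():
            if name.startswith(PRIVATE_PREFIXES):
                raise PrivacyViolation(
                    f"upload contains private parameter {name!r}")


def aggregate(server: ParamSet, clients: List[ParamSet], omega_c: float,
              omega_k) -> ParamSet:
    """Metadata-constrained aggregation:
    ``omega_c * theta_server + (1 - omega_c) * sum_k omega_k * theta_k``."""
    if not 0.0 <= omega_c <= 1.0:
        raise ValueError("omega_c must lie in [0, 1]")
    omega_k = np.asarray(omega_k, dtype=np.float64)
    if len(omega_k) != len(clients):
        raise ValueError("one omega_k per client required")
    if np.any(omega_k < 0) or abs(omega_k.sum() - 1.0) > 1e-9:
        raise ValueError("omega_k must be nonnegative and sum to 1")
    if omega_c == 1.0:
        return server.copy()
    mix = weighted_sum(clients, omega_k)
    if omega_c == 0.0:
        return mix
    return server.scale(omega_c).add(mix.scale(1.0 - omega_c))


def broadcast(trunk: ParamSet, prompt: ParamSet, clients: List[ClientState]):
    """Copy the global shared-model parameters into every client."""
    for c in clients:
        c.receive(trunk.copy(), prompt.copy())


def weight_divergence(theta_fl: ParamSet, theta_local: ParamSet) -> float:
    """Sum over layers of ||theta_FL^l - theta_local^l|| / ||theta_local^l||
    (Euclidean norm per named tensor)."""
    theta_fl._check_aligned(theta_local)
    total = 0.0
    for name in theta_fl.keys():
        denom = float(np.linalg.norm(theta_local[name]))
        if denom == 0.0:
            raise ValueError(f"local layer {name!r} has zero norm")
        total += float(np.linalg.norm(theta_fl[name] - theta_local[name])) / denom
    return total


@dataclass
class FederationState:
    round: int
    server_trunk: ParamSet
    server_prompt: ParamSet
    clients: List[ClientState]
    history: List[dict] = field(default_factory=list)
    final_report: dict = field(default_factory=dict)


def run_federation(cfg: FederationConfig, datasets: List[ClientDataset],
                   pool: Optional[MetadataPool]) -> FederationState:
    """Execute T rounds of the federated training loop; deterministic per seed."""
    if not datasets:
        raise ValueError("at least one client dataset is required")
    use_meta = cfg.mode in ("fedm2ct", "no_cpml", "no_prompt")
    if use_meta and (pool is None or len(pool) == 0):
        raise ValueError("metadata pool required unless the metamodel is disabled")

    model_cfg = cfg.model
    if cfg.mode in ("no_prompt", "no_cpml", "fedavg_baseline"):
        model_cfg = replace(model_cfg, use_prompt=False)

    rng = np.random.default_rng(cfg.seed)
    clients = [ClientState(ds, cfg, model_cfg, seed=cfg.seed + 17 * i)
               for i, ds in enumerate(datasets)]
    omega_k = _client_weights(cfg, len(clients))

    meta_model = SharedModel(model_cfg, seed=cfg.seed + 101)
    opt_meta = Adam(meta_model.named_parameters(), cfg.opt_meta)

    # all parties start from the same shared-model initialisation
    trunk = meta_model.trunk_paramset("meta")
    prompt = meta_model.prompt_paramset("meta_prompt")
    for c in clients:
        c.receive(ParamSet(trunk.entries, "shared"),
                  ParamSet(prompt.entries, "prompt"))
        if c.shadow is not None:
            c.shadow.load_trunk(ParamSet(trunk.entries, "shared"))
            c.shadow.load_prompt(ParamSet(prompt.entries, "prompt"))

    state = FederationState(0, trunk, prompt, clients)
    omega_c = cfg.omega_c if use_meta else 0.0

    for t in range(cfg.T):
        round_log = {"round": t}
        for i, c in enumerate(clients):
            step_seed = int(rng.integers(0, 2 ** 31 - 1))
            tc, tsh = mutual_round(
                c, cfg.iters_local, step_seed,
                shadow_model=c.shadow, shadow_optimizer=c.opt_shadow)
            round_log[f"{c.id}/client_loss"] = tc[-1]
            round_log[f"{c.id}/shared_loss"] = tsh[-1]
        if use_meta:
            meta_trace = meta_update(meta_model, opt_meta, pool,
                                     cfg.iters_meta,
                                     int(rng.integers(0, 2 ** 31 - 1)),
                                     batch_size=cfg.batch_size)
            round_log["meta_loss"] = meta_trace[-1]

        uploads = [c.make_upload() for c in clients]
        for up in uploads:
            validate_upload(up)

        server_trunk = (meta_model.trunk_paramset("meta") if use_meta
                        else uploads[0]["shared"].scale(0.0))
        server_prompt = (meta_model.prompt_paramset("meta_prompt") if use_meta
                         else uploads[0]["prompt"].scale(0.0))
        trunk = aggregate(server_trunk,
                          [u["shared"] for u in uploads], omega_c, omega_k)
        prompt = aggregate(server_prompt,
                           [u["prompt"] for u in uploads], omega_c, omega_k)
        broadcast(trunk, prompt, clients)
        if use_meta:
            # the aggregated model is also the next-round metamodel
            meta_model.load_trunk(ParamSet(trunk.entries, "meta"))
            meta_model.load_prompt(ParamSet(prompt.entries, "meta_prompt"))

        if cfg.track_divergence:
            divs = [weight_divergence(trunk,
                                      c.shadow.trunk_paramset("shared"))
                    for c in clients]
            round_log["weight_divergence"] = float(np.mean(divs))
        for c in clients:
            val = c.evaluate("val")
            round_log[f"{c.id}/val_psnr"] = val["model"]["psnr"]
            round_log[f"{c.id}/val_fbp_psnr"] = val["fbp"]["psnr"]
        state.history.append(round_log)
        state.round = t + 1
        state.server_trunk, state.server_prompt = trunk, prompt

    report = {"clients": {c.id: c.evaluate("test") for c in clients}}
    if cfg.track_divergence and state.history:
        report["weight_divergence"] = state.history[-1].get("weight_divergence")
    state.final_report = report
    return state
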