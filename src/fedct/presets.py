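"""Desk-scale cohort presets (situation 1/2/3) and the federation builder.

The three shipped presets mirror the three study situations: a low-mAs-only
federation, a mixed low-mAs / limited-angle / sparse-view federation, and a
paired/unpaired federation.  Sizes (64-px grids, 20 images per client, 10
rounds of 20 iterations) are chosen so a full run takes a couple of minutes
on one CPU core; learning rates are scaled up accordingly (the study-scale
defaults in :mod:`fedct.objectives` assume tens of thousands of iterations).
"""

from __future__ import annotations

import importlib.resources as resources
from typing import Optional

import yaml

from .cohort import (ClientDataset, MetadataPool, build_client_dataset,
                     build_metadata_pool, default_protocol_family)
from .federation import FederationConfig
from .geometry import ScanGeometry
from .lowdose import DoseProtocol
from .models import ModelConfig
from .objectives import LossWeights, OptimizerSettings

PRESETS = ("situation1", "situation2", "situation3")


def load_preset(name: str) -> dict:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    ref = resources.files("fedct").joinpath(f"presets/{name}.yaml")
    return yaml.safe_load(ref.read_text())


def build_situation(situation=2, seed: int = 0, mode: str = "fedm2ct",
                    omega_c: Optional[float] = None,
                    delta: Optional[float] = None,
                    alpha_k: Optional[float] = None,
                    T: Optional[int] = None,
                    n_images: Optional[int] = None,
                    track_divergence: bool = True,
                    preset: Optional[dict] = None):
    """Instantiate (FederationConfig, client datasets, metadata pool) for a
    preset situation, with optional hyperparameter overrides."""
    if preset is None:
        name = situation if isinstance(situation, str) else f"situation{situation}"
        preset = load_preset(name)
    fed = preset["federation"]
    loss = preset["loss"]
    model_cfg = ModelConfig(**preset["model"])
    weights = LossWeights(
        delta=delta if delta is not None else loss["delta"],
        alpha_k=alpha_k if alpha_k is not None else loss["alpha_k"],
        epsilon_k=loss.get("epsilon_k_paired", 0.0))
    cfg = FederationConfig(
        T=T if T is not None else fed["T"],
        iters_local=fed["iters_local"],
        iters_shared=fed["iters_shared"],
        iters_meta=fed["iters_meta"],
        omega_c=omega_c if omega_c is not None else fed["omega_c"],
        mode=mode,
        seed=seed,
        batch_size=fed["batch_size"],
        model=model_cfg,
        weights=weights,
        opt_local=OptimizerSettings(learning_rate=fed["learning_rate_local"]),
        opt_meta=OptimizerSettings(learning_rate=fed["learning_rate_meta"]),
        track_divergence=track_divergence,
    )
    n_img = n_images if n_images is not None else preset["n_images"]
    datasets = []
    for i, block in enumerate(preset["clients"]):
        geom = ScanGeometry.from_config(block["geometry"])
        proto = DoseProtocol.from_config(block)
        datasets.append(build_client_dataset(
            block["id"], geom, proto, n_img, seed=seed * 1009 + 31 * i + 7))
    pool_cfg = preset["metadata_pool"]
    family = default_protocol_family(pool_cfg["family"])
    pool_geom = ScanGeometry.from_config(preset["clients"][0]["geometry"])
    pool = build_metadata_pool(pool_cfg["n_pairs"], family, pool_geom,
                               seed=seed * 1013 + 501)
    return cfg, datasets, pool
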