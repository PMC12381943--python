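"""Image-quality metrics and the ablation/sweep harness.

PSNR and RMSE are closed-form; SSIM wraps the standard windowed formulation
(Gaussian window 11, sigma 1.5, stabilisers (0.01*range)^2 and
(0.03*range)^2).  Metrics are computed in HU over the full field of view by
default, with the per-image data range max(ref) - min(ref).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .geometry import ImageGrid

PSNR_INF = math.inf


def _pair(test, ref):
    t = test.data if isinstance(test, ImageGrid) else np.asarray(test, float)
    r = ref.data if isinstance(ref, ImageGrid) else np.asarray(ref, float)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {r.shape}")
    return t, r


def rmse(test, ref) -> float:
    """Root-mean-square error, same units as the images."""
    t, r = _pair(test, ref)
    return float(np.sqrt(np.mean((t - r) ** 2)))


def psnr(test, ref, data_range: Optional[float] = None) -> float:
    """10*log10(range^2 / MSE) in dB; infinite for identical images."""
    t, r = _pair(test, ref)
    if data_range is None:
        data_range = float(r.max() - r.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse_val = float(np.mean((t - r) ** 2))
    if mse_val == 0:
        return PSNR_INF
    return 10.0 * math.log10(data_range ** 2 / mse_val)


def ssim(test, ref, data_range: Optional[float] = None) -> float:
    """Mean structural similarity (Gaussian window 11, sigma 1.5)."""
    t, r = _pair(test, ref)
    if min(t.shape) < 11:
        raise ValueError("image smaller than the 11-pixel SSIM window")
    if data_range is None:
        data_range = float(r.max() - r.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(structural_similarity(
        t, r, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, K1=0.01, K2=0.03))


def evaluate_pair_hu(test_mu: ImageGrid, ref_mu: ImageGrid) -> dict:
    """PSNR/SSIM/RMSE in HU with the reference's own data range."""
    t = test_mu.to_hu()
    r = ref_mu.to_hu()
    return {"psnr": psnr(t, r), "ssim": ssim(t, r), "rmse": rmse(t, r)}


@dataclass
class MetricReport:
    """Per-image metric rows plus aggregates recomputable from them."""

    rows: List[dict] = field(default_factory=list)

    def add(self, **metrics):
        self.rows.append(metrics)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregate(self, by=None) -> pd.DataFrame:
        df = self.frame()
        num = df.select_dtypes("number")
        if by:
            return df.groupby(by)[num.columns.difference([by], sort=False)
                                  .tolist()].agg(["mean", "std"])
        return num.agg(["mean", "std"])


def run_ablation_sweep(base_config: dict, parameter_grid: dict,
                       seeds=(0,)) -> pd.DataFrame:
    """Run toy federations over a grid of {omega_c, delta, alpha_k, CP}.

    ``parameter_grid`` maps parameter name -> list of values; each cell
    varies one parameter from the base configuration, mirroring a
    one-at-a-time ablation.  Returns mean test PSNR/SSIM per cell.
    """
    from .federation import FederationConfig, run_federation
    from .presets import build_situation

    rows = []
    for param, values in parameter_grid.items():
        for value in values:
            for seed in seeds:
                cfg_dict = dict(base_config)
                if param == "omega_c":
                    if not 0.0 <= value <= 1.0:
                        raise ValueError("omega_c must lie in [0, 1]")
                    cfg_dict["omega_c"] = value
                elif param == "delta":
                    cfg_dict["delta"] = value
                elif param == "alpha_k":
                    cfg_dict["alpha_k"] = value
                elif param == "CP":
                    cfg_dict["mode"] = ("fedm2ct" if value else "no_prompt")
                else:
                    raise ValueError(f"unknown sweep parameter {param!r}")
                cfg_dict["seed"] = seed
                fed_cfg, clients, pool = build_situation(**cfg_dict)
                state = run_federation(fed_cfg, clients, pool)
                rep = state.final_report
                rows.append({
                    "parameter": param, "value": value, "seed": seed,
                    "psnr": np.mean([c["model"]["psnr"]
                                     for c in rep["clients"].values()]),
                    "ssim": np.mean([c["model"]["ssim"]
                                     for c in rep["clients"].values()]),
                })
    df = pd.DataFrame(rows)
    return df.groupby(["parameter", "value"])[["psnr", "ssim"]].mean().reset_index()
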