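"""Synthetic concentration-response data with known ground truth.

Emulates plate-style screening series: half-log (0.5 log10) concentration
spacing, a handful of concentrations with a few replicates each, a known
generating model, and heavy-tailed (t with 4 df) or normal noise in
either response direction.  The default design — 8 concentrations from
0.03 µM at 0.5 log10 spacing, 3 replicates, t(4) noise of scale 5
response units — is representative of the screening designs the curve
pipeline targets.

Everything is deterministic under its seed; generators never emit
non-positive concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import ConcRespSeries
from .models import MODELS, evaluate

__all__ = ["SimConfig", "simulate_series", "simulate_endpoint", "simulate_burst", "conc_grid"]


def conc_grid(n_conc: int = 8, conc_min: float = 0.03, spacing: float = 0.5) -> np.ndarray:
    """Half-log-style test concentrations (µM)."""
    return conc_min * 10.0 ** (spacing * np.arange(n_conc))


@dataclass(frozen=True)
class SimConfig:
    """Recipe for one synthetic series; identical configs (including the
    seed) produce byte-identical output."""

    n_conc: int = 8
    conc_spacing: float = 0.5
    conc_min: float = 0.03
    n_rep: int = 3
    model: str = "hill"
    params: dict = field(default_factory=lambda: {"tp": 50.0, "ga": 1.0, "p": 2.0})
    noise_model: str = "t4"
    noise_scale: float = 5.0
    direction: int = 1
    seed: int = 0
    sample_id: str = "sim"
    endpoint_id: str = "ep"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model: {self.model!r}")
        if self.noise_model not in ("t4", "normal"):
            raise ValueError("noise_model must be 't4' or 'normal'")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.n_conc < 1 or self.n_rep < 1 or self.conc_min <= 0:
            raise ValueError("invalid design: need n_conc, n_rep >= 1 and conc_min > 0")


def _noise(rng: np.random.Generator, n: int, model: str, scale: float) -> np.ndarray:
    if scale == 0:
        return np.zeros(n)
    if model == "t4":
        return scale * rng.standard_t(4, size=n)
    return rng.normal(0.0, scale, size=n)


def simulate_series(config: SimConfig) -> ConcRespSeries:
    """One series: model curve plus noise on the replicate grid."""
    conc = np.repeat(conc_grid(config.n_conc, config.conc_min, config.conc_spacing),
                     config.n_rep)
    if config.model == "constant":
        signal = np.zeros(conc.size)
    else:
        signal = np.asarray(evaluate(config.model, config.params, conc), dtype=float)
    rng = np.random.default_rng(config.seed)
    resp = config.direction * signal + _noise(rng, conc.size, config.noise_model,
                                              config.noise_scale)
    return ConcRespSeries(config.sample_id, config.endpoint_id, conc, resp)


def simulate_endpoint(
    n_samples: int,
    model_mix: dict | None = None,
    base_config: SimConfig = SimConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format endpoint table plus its generating truth.

    ``model_mix`` maps model ids to either a probability (models are
    drawn per sample) or to parameter dicts via entries of the form
    ``{"model": prob}``; by default every sample uses the base config's
    model and parameters.  Returns ``(mc3, truth)`` where mc3 holds one
    row per well (aeid, spid, conc, resp, wllt) — its two lowest
    concentration groups are the baseline wells for BMAD/onesd — and
    truth one row per sample recording the generating model, parameters
    and direction.
    """
    rng = np.random.default_rng(seed)
    models = list(model_mix) if model_mix else [base_config.model]
    probs = None
    if model_mix:
        probs = np.array([model_mix[m] for m in models], dtype=float)
        probs = probs / probs.sum()
    rows = []
    truth = []
    for i in range(n_samples):
        model = models[int(rng.choice(len(models), p=probs))] if probs is not None else models[0]
        cfg = replace(
            base_config,
            model=model,
            params=base_config.params if model == base_config.model else _default_params(model),
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"spid_{i:04d}",
        )
        series = simulate_series(cfg)
        for c, r in zip(series.conc, series.resp):
            rows.append((cfg.endpoint_id, cfg.sample_id, c, r, "t"))
        truth.append(
            {
                "aeid": cfg.endpoint_id,
                "spid": cfg.sample_id,
                "model": cfg.model,
                "direction": cfg.direction,
                "noise_scale": cfg.noise_scale,
                **{f"true_{k}": v for k, v in cfg.params.items()},
            }
        )
    mc3 = pd.DataFrame(rows, columns=["aeid", "spid", "conc", "resp", "wllt"])
    return mc3, pd.DataFrame(truth)


def _default_params(model: str) -> dict:
    """Representative generating parameters per model family."""
    return {
        "constant": {},
        "poly1": {"a": 1.5},
        "poly2": {"a": 20.0, "b": 30.0},
        "power": {"a": 10.0, "p": 0.8},
        "hill": {"tp": 50.0, "ga": 1.0, "p": 2.0},
        "gnls": {"tp": 50.0, "ga": 0.3, "p": 2.0, "la": 30.0, "q": 2.0},
        "exp2": {"a": 4.0, "b": 20.0},
        "exp3": {"a": 8.0, "b": 20.0, "p": 0.8},
        "exp4": {"tp": 50.0, "ga": 1.0},
        "exp5": {"tp": 50.0, "ga": 1.0, "p": 1.2},
    }[model]


def simulate_burst(
    n_chem: int,
    n_endpoints: int,
    median_log10_ac50: float = 0.5,
    dispersion: float = 0.15,
    hit_rate: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Chemical x burst-endpoint table with planted ground truth.

    Each chemical's active AC50s are drawn symmetrically around its
    planted median (log10-µM) with the requested dispersion, so the
    per-chemical burst point recovers the median and the downstream
    global MAD is controlled by ``dispersion``.
    """
    if n_endpoints < 1:
        raise ValueError("need at least one endpoint")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_chem):
        chem = f"chem_{i:03d}"
        n_active = int(round(hit_rate * n_endpoints))
        # symmetric offsets around the planted median preserve it exactly
        offsets = np.linspace(-1.0, 1.0, n_active) * dispersion * 1.5 if n_active else []
        active_flags = np.zeros(n_endpoints, bool)
        active_flags[:n_active] = True
        rng.shuffle(active_flags)
        j_active = 0
        for j in range(n_endpoints):
            active = bool(active_flags[j])
            if active:
                ac50 = 10.0 ** (median_log10_ac50 + offsets[j_active])
                j_active += 1
            else:
                ac50 = np.nan
            rows.append(
                {
                    "chemical_id": chem,
                    "endpoint_id": f"burst_{j:03d}",
                    "tested": True,
                    "active": active,
                    "ac50": ac50,
                    "winning_model": "hill",
                    "proliferation_direction": False,
                }
            )
    return pd.DataFrame(rows)
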