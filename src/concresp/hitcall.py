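"""Continuous hit calling.

The activity call for a series is a continuous value in [0, 1], the
product of three proportional weights, each a confidence that one
requirement for genuine activity is met:

``w_aic``
    the winning model beats the constant (zero-response) model on AIC —
    the Akaike weight of the winner in a two-model comparison,
    ``1 / (1 + exp((AIC_win - AIC_const)/2))``.  When the constant model
    has the lower AIC the weight, and hence the hit call, approaches 0.
``w_median``
    at least one concentration has a median response exceeding the
    cutoff in absolute value.  Under the fitted t(4) error law the
    median of n replicates at a concentration is treated as
    t(4)-distributed around the modeled response with scale
    ``exp(er)/sqrt(n)``; the weight is the largest single-concentration
    exceedance probability.  The ``v4.0_replicate`` dialect instead
    scores individual replicate exceedance (identical when n_rep = 1).
``w_top``
    the modeled top exceeds the cutoff — a signed-root likelihood-ratio
    tail probability comparing the free fit against the fit with |top|
    profiled at the cutoff.

A series that could not be fit (winning model "none") has hitc = 0.
The continuous value is binarized at a user-settable threshold,
0.90 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from scipy.stats import t as t_dist

from .baseline import CutoffSpec
from .fitting import ConcRespSeries, ModelFit, WinnerResult, profiled_loglik
from .models import MODELS, _eval_raw, model_top

__all__ = [
    "HitResult",
    "DEFAULT_HIT_THRESHOLD",
    "MEDIAN_DIALECTS",
    "continuous_hitcall",
    "binarize",
]

DEFAULT_HIT_THRESHOLD = 0.90
MEDIAN_DIALECTS = ("v4.1_median", "v4.0_replicate")


@dataclass(frozen=True)
class HitResult:
    """Continuous hit call with its three weights and the binary call."""

    hitc: float
    w_aic: float
    w_median: float
    w_top: float
    active: bool


def _w_aic(aic_winner: float, aic_constant: float) -> float:
    # two-model Akaike weight; guarded against exp overflow
    delta = 0.5 * (aic_winner - aic_constant)
    if delta > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(delta))


def _w_median(series: ConcRespSeries, fit: ModelFit, coff: float, dialect: str) -> float:
    sigma = math.exp(fit.params["er"])
    if dialect == "v4.1_median":
        uniq, _, cnt = series.groups()
        mu = _eval_raw(fit.model_id, fit.params, uniq)
        scale = sigma / np.sqrt(cnt)
    elif dialect == "v4.0_replicate":
        mu = _eval_raw(fit.model_id, fit.params, series.conc)
        scale = np.full(mu.shape, sigma)
    else:
        raise ValueError(f"unknown w_median dialect: {dialect!r}")
    scale = np.maximum(scale, 1e-300)
    p_hi = t_dist.sf((coff - mu) / scale, df=4)
    p_lo = t_dist.cdf((-coff - mu) / scale, df=4)
    return float(np.max(p_hi + p_lo))


def _w_top(series: ConcRespSeries, fit: ModelFit, coff: float) -> float:
    spec = MODELS[fit.model_id]
    top_sign = 1.0 if fit.top >= 0 else -1.0
    scale_name = spec.scale_param
    conc_range = series.conc_range

    def scale_for(shapes: dict) -> float | None:
        # scale the curve so its in-range |top| equals the cutoff
        unit = dict(shapes)
        unit[scale_name] = 1.0
        try:
            t_unit, _ = model_top(fit.model_id, unit, conc_range)
        except (ValueError, FloatingPointError):
            return None
        if t_unit == 0 or not np.isfinite(t_unit):
            return None
        return top_sign * coff / abs(t_unit)

    ll1 = fit.loglik
    ll0 = profiled_loglik(series, fit.model_id, fit.params, scale_for)
    lr = max(ll1 - ll0, 0.0)
    z = math.copysign(math.sqrt(2.0 * lr), abs(fit.top) - coff)
    return float(norm.cdf(z))


def continuous_hitcall(
    series: ConcRespSeries,
    winner: WinnerResult,
    cutoff: CutoffSpec,
    dialect: str = "v4.1_median",
    threshold: float = DEFAULT_HIT_THRESHOLD,
) -> HitResult:
    """Continuous hit call for one fitted series.

    Returns the exact product of the three weights; degenerate inputs
    (no winning model) yield hitc = 0.
    """
    coff = cutoff.coff
    if coff <= 0:
        raise ValueError("cutoff must be strictly positive")
    fit = winner.winner
    if fit is None:
        return HitResult(0.0, 0.0, 0.0, 0.0, False)
    wa = _w_aic(fit.aic, winner.aic_constant)
    wm = _w_median(series, fit, coff, dialect)
    wt = _w_top(series, fit, coff)
    hitc = wa * wm * wt
    return HitResult(hitc, wa, wm, wt, binarize(hitc, threshold))


def binarize(hitc: float, threshold: float = DEFAULT_HIT_THRESHOLD) -> bool:
    """Active iff hitc >= threshold; hitc must lie in [0, 1]."""
    if not (0.0 <= hitc <= 1.0):
        raise ValueError(f"hitc must lie in [0, 1], got {hitc}")
    return hitc >= threshold
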