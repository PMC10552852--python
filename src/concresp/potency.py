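"""Potency estimation: ACxx, ACC, ACB, and the benchmark dose.

All potency metrics are concentrations (µM) at which the winning model
first reaches a response level, found by inversion in log10-conc space:

* AC5/AC10/AC50/AC95 — 5/10/50/95% of the curve's efficacy top.  For the
  asymptotic families (hill, exp4, exp5) the efficacy top is the model
  asymptote ``tp`` (so AC50 = ga exactly); for gnls it is the interior
  peak response; for the unbounded families (poly1, poly2, power, exp2,
  exp3) it is the modeled response at the highest tested concentration.
* ACC — response at the endpoint's efficacy cutoff.
* ACB — response first reaching the baseline region boundary, 3*BMAD.
* BMD — response at the benchmark response, BMR = 1.349 * onesd.

A metric is absent (None), never clamped, when its level is not
attained.  The search window extends beyond the tested range (down four
decades, up four decades) because informative fits can place e.g. the
AC50 below the lowest tested concentration; the fit-category logic
depends on exactly that comparison.

The BMD carries a 90% profile-likelihood confidence interval
[BMDL, BMDU]: the model is reparameterized so the BMD is explicit (the
scale parameter is solved from f(BMD) = BMR at each candidate BMD), the
remaining parameters are re-optimized, and the bounds are the
concentrations where the profiled log-likelihood drops chi2_1(0.90)/2
(about 1.3528) below its maximum.  A bound that cannot be bracketed
within two decades of the tested range is reported absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .baseline import CutoffSpec
from .fitting import ConcRespSeries, ModelFit, profiled_loglik
from .models import MODELS, _eval_raw, inverse_conc, model_top

__all__ = ["PotencySet", "ACXX_LEVELS", "compute_potencies", "bmd_bounds", "reference_top"]

ACXX_LEVELS = {"ac5": 0.05, "ac10": 0.10, "ac50": 0.50, "ac95": 0.95}

#: inversion window, in decades, beyond the tested concentration range
_POTENCY_DECADES = 4.0
#: bracket window for BMD bounds, in decades beyond the tested range
_BOUND_DECADES = 2.0


@dataclass(frozen=True)
class PotencySet:
    """Potency metrics for one winning fit (µM; None when unattained)."""

    ac5: float | None = None
    ac10: float | None = None
    ac50: float | None = None
    ac95: float | None = None
    acb: float | None = None
    acc: float | None = None
    bmd: float | None = None
    bmdl: float | None = None
    bmdu: float | None = None
    bmr: float = math.nan


def reference_top(fit: ModelFit, conc_range: tuple[float, float]) -> float:
    """Signed efficacy top the ACxx levels are fractions of."""
    m = fit.model_id
    if m in ("hill", "exp4", "exp5"):
        return float(fit.params["tp"])
    if m == "gnls":
        cmin, cmax = conc_range
        window = (cmin * 10.0**-_POTENCY_DECADES, cmax * 10.0**_POTENCY_DECADES)
        top, _ = model_top(m, fit.params, window)
        return top
    return float(fit.top)


def _invert(fit: ModelFit, target: float, conc_range: tuple[float, float]) -> float | None:
    cmin, cmax = conc_range
    window = (cmin * 10.0**-_POTENCY_DECADES, cmax * 10.0**_POTENCY_DECADES)
    return inverse_conc(fit.model_id, fit.params, target, window, n_grid=1024)


def compute_potencies(
    fit: ModelFit | None,
    cutoff: CutoffSpec,
    conc_range: tuple[float, float],
) -> PotencySet:
    """Derive the full potency set from a winning fit.

    Absent or failed fits (and the constant model) yield an all-absent
    set.  Levels are signed with the direction of the efficacy top so
    loss-direction curves invert against their (negative) levels.
    """
    bmr = cutoff.bmr
    if fit is None or not fit.success or fit.model_id == "constant":
        return PotencySet(bmr=bmr)
    ref = reference_top(fit, conc_range)
    if ref == 0 or not np.isfinite(ref):
        return PotencySet(bmr=bmr)
    sign = 1.0 if ref > 0 else -1.0

    def at_level(level: float) -> float | None:
        if level <= 0 or level > abs(ref) * (1.0 + 1e-9):
            return None
        return _invert(fit, sign * min(level, abs(ref)), conc_range)

    values = {name: at_level(frac * abs(ref)) for name, frac in ACXX_LEVELS.items()}
    acc = at_level(cutoff.coff)
    acb = at_level(3.0 * cutoff.bmad)
    bmd = at_level(bmr)
    bmdl = bmdu = None
    return PotencySet(acb=acb, acc=acc, bmd=bmd, bmdl=bmdl, bmdu=bmdu, bmr=bmr, **values)


def _bmd_profile(series: ConcRespSeries, fit: ModelFit, target: float):
    """Profiled log-likelihood as a function of log10(BMD)."""
    scale_name = MODELS[fit.model_id].scale_param
    state: dict = {"warm": None}

    def prof(lbmd: float) -> float:
        bmd_c = 10.0**lbmd

        def scale_for(shapes: dict) -> float | None:
            unit = dict(shapes)
            unit[scale_name] = 1.0
            with np.errstate(over="ignore", invalid="ignore"):
                g = float(_eval_raw(fit.model_id, unit, np.array([bmd_c]))[0])
            if g == 0 or not np.isfinite(g):
                return None
            return target / g

        # warm-start from the neighboring profile point: the constrained
        # optimum drifts smoothly along the profile
        extra = (state["warm"],) if state["warm"] is not None else ()
        ll, params = profiled_loglik(series, fit.model_id, fit.params, scale_for,
                                     extra_starts=extra, return_params=True)
        if np.isfinite(ll):
            state["warm"] = params
        return ll

    return prof


def bmd_bounds(
    series: ConcRespSeries,
    fit: ModelFit,
    bmr: float,
    level: float = 0.90,
) -> tuple[float | None, float | None]:
    """Profile-likelihood BMD interval (BMDL, BMDU) at the given level.

    Either bound is None when the profiled likelihood never drops below
    the threshold inside the bracket window — the interval is effectively
    unbounded on that side (typical of very noisy, flat data) and is
    reported as absent rather than clamped.
    """
    ref = reference_top(fit, series.conc_range)
    if ref == 0 or not np.isfinite(ref):
        return None, None
    sign = 1.0 if ref > 0 else -1.0
    if bmr <= 0 or bmr > abs(ref):
        return None, None
    target = sign * bmr
    bmd = _invert(fit, target, series.conc_range)
    if bmd is None:
        return None, None
    cmin, cmax = series.conc_range
    l_lo = math.log10(cmin) - _BOUND_DECADES
    l_hi = math.log10(cmax) + _BOUND_DECADES
    lhat = math.log10(bmd)
    drop = chi2.ppf(level, 1) / 2.0
    prof = _bmd_profile(series, fit, target)
    ll_ref = max(fit.loglik, prof(lhat))
    thresh = ll_ref - drop

    def g(l: float) -> float:
        return prof(l) - thresh

    def find(direction: int) -> float | None:
        limit = l_lo if direction < 0 else l_hi
        prev_l = lhat
        while True:
            l = prev_l + direction * 0.25
            if (l - limit) * direction > 0:
                l = limit
            if g(l) < 0:
                try:
                    root = brentq(g, min(prev_l, l), max(prev_l, l), xtol=1e-4)
                except ValueError:
                    return None
                return float(10.0**root)
            if l == limit:
                return None
            prev_l = l

    bmdl = find(-1)
    bmdu = find(+1)
    return bmdl, bmdu
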