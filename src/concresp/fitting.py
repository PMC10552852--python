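"""Robust maximum-likelihood curve fitting and winner selection.

Each concentration-response series is fit with all ten model families
under a Student-t likelihood with 4 degrees of freedom and scale
``exp(er)`` — a heavy-tailed error law that keeps single outlying wells
from dominating the fit.  Fitting is bidirectional by default (the scale
parameter ``tp``/``a`` is free in sign); endpoints that are only
meaningful in one direction can be constrained to gain or loss.

The winning model is the successful non-constant fit with the lowest
AIC.  The constant model is always fit but can never win; its AIC is
kept as the reference for the first hit-call weight.  An exact AIC tie
is broken in favor of the model with fewer parameters, and any residual
tie by a fixed model-order precedence.

Series with fewer than four distinct concentrations are not fit at all
(winning model "none").

Optimization runs a bounded quasi-Newton (L-BFGS-B) from three
deterministic, data-derived starting points per model, with central
finite differences so that fitting a series and its sign-mirrored copy
yields exactly mirrored results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import GNLS_MIN_WIDTH, MODELS, _eval_raw, model_top

__all__ = [
    "ConcRespSeries",
    "ModelFit",
    "WinnerResult",
    "MODEL_PRECEDENCE",
    "MIN_CONC_FOR_FIT",
    "t4_loglik",
    "fit_one",
    "fit_constant",
    "fit_all",
    "profiled_loglik",
]

#: minimum number of distinct concentrations required to attempt a fit
MIN_CONC_FOR_FIT = 4

#: tie-break order after parameter count (simplest families first)
MODEL_PRECEDENCE = (
    "poly1",
    "power",
    "exp2",
    "exp4",
    "hill",
    "exp3",
    "exp5",
    "poly2",
    "gnls",
)

#: models fit to every series (the constant model is handled separately)
FIT_MODELS = MODEL_PRECEDENCE

_DIRECTIONS = ("bidirectional", "gain_only", "loss_only")

# log of t(df=4) density normalizing constant
_T4_CONST = math.lgamma(2.5) - math.lgamma(2.0) - 0.5 * math.log(4.0 * math.pi)

_ER_MIN = -12.0
_AIC_TIE_TOL = 1e-9


def t4_loglik(resid: np.ndarray, er: float) -> float:
    """Log-likelihood of residuals under t(4) errors with scale exp(er)."""
    with np.errstate(over="ignore"):
        z2 = np.square(resid * math.exp(-er))
        return float(resid.size * (_T4_CONST - er) - 2.5 * np.log1p(0.25 * z2).sum())


@dataclass(frozen=True)
class ConcRespSeries:
    """One sample x endpoint concentration-response series.

    Replicates are encoded as repeated values in ``conc``; the number of
    distinct concentrations drives the short-series rules downstream.
    """

    sample_id: str
    endpoint_id: str
    conc: np.ndarray
    resp: np.ndarray
    direction: str = "bidirectional"

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.resp, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "resp", resp)
        if conc.ndim != 1 or conc.shape != resp.shape or conc.size < 1:
            raise ValueError("conc and resp must be equal-length 1-D arrays")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")

    @property
    def n_conc(self) -> int:
        return int(np.unique(self.conc).size)

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(self.conc.min()), float(self.conc.max())

    def groups(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Distinct concentrations with their response medians and counts."""
        uniq = np.unique(self.conc)
        med = np.empty_like(uniq)
        cnt = np.empty(uniq.size, dtype=int)
        for i, c in enumerate(uniq):
            sel = self.resp[self.conc == c]
            med[i] = np.median(sel)
            cnt[i] = sel.size
        return uniq, med, cnt

    def mirrored(self) -> "ConcRespSeries":
        return ConcRespSeries(
            self.sample_id, self.endpoint_id, self.conc, -self.resp, self.direction
        )


@dataclass(frozen=True)
class ModelFit:
    """One model's fit to one series."""

    model_id: str
    params: dict
    loglik: float
    aic: float
    rmse: float
    top: float
    top_conc: float
    success: bool
    message: str = ""

    @property
    def n_params(self) -> int:
        return MODELS[self.model_id].n_params


@dataclass(frozen=True)
class WinnerResult:
    """All fits for a series plus the AIC-selected winner.

    ``winning_model`` is None for series that cannot be fit (fewer than
    four distinct concentrations, or every optimizer attempt failed).
    The constant model appears in ``fits`` but is never the winner.
    """

    winning_model: str | None
    fits: dict
    aic_constant: float

    @property
    def winner(self) -> ModelFit | None:
        if self.winning_model is None:
            return None
        return self.fits[self.winning_model]


# ---------------------------------------------------------------------------
# working-parameter transforms
#
# Concentration-scale parameters (ga, la, b) are optimized as log10 values;
# the gnls loss AC50 is optimized as the width w = log10(la) - log10(ga)
# with a hard lower bound at GNLS_MIN_WIDTH, making the minimum-width rule
# a box constraint.

_LOG_PARAMS = frozenset({"ga", "la", "b"})


def _working_names(model_id: str, skip: str | None = None) -> list[str]:
    names = []
    for name in MODELS[model_id].param_names:
        if name == skip:
            continue
        if model_id == "gnls" and name == "la":
            names.append("w")
        elif name in _LOG_PARAMS:
            names.append("l" + name)
        else:
            names.append(name)
    names.append("er")
    return names


def _to_natural(model_id: str, wnames: Sequence[str], vec: np.ndarray) -> dict:
    nat: dict[str, float] = {}
    for name, v in zip(wnames, vec):
        if name == "w":
            nat["_w"] = float(v)
        elif name.startswith("l") and name[1:] in _LOG_PARAMS:
            nat[name[1:]] = 10.0 ** float(v)
        else:
            nat[name] = float(v)
    if "_w" in nat:
        nat["la"] = nat["ga"] * 10.0 ** nat.pop("_w")
    return nat


def _from_natural(model_id: str, wnames: Sequence[str], params: Mapping[str, float]) -> np.ndarray:
    vec = np.empty(len(wnames))
    for i, name in enumerate(wnames):
        if name == "w":
            vec[i] = math.log10(params["la"]) - math.log10(params["ga"])
        elif name.startswith("l") and name[1:] in _LOG_PARAMS:
            vec[i] = math.log10(params[name[1:]])
        else:
            vec[i] = params[name]
    return vec


def _bounds(series: ConcRespSeries, wnames: Sequence[str]) -> list[tuple[float, float]]:
    cmin, cmax = series.conc_range
    lo, hi = math.log10(cmin) - 1.0, math.log10(cmax) + 1.0
    rmax = float(np.max(np.abs(series.resp)))
    amp = 12.0 * rmax if rmax > 0 else 1.0
    if series.direction == "gain_only":
        scale_bounds = (0.0, amp)
    elif series.direction == "loss_only":
        scale_bounds = (-amp, 0.0)
    else:
        scale_bounds = (-amp, amp)
    er_hi = math.log(max(rmax, 1.0)) + 2.0
    out = []
    for name in wnames:
        if name in ("tp", "a"):
            out.append(scale_bounds)
        elif name in ("p", "q"):
            out.append((0.3, 8.0))
        elif name == "w":
            out.append((GNLS_MIN_WIDTH, (hi - lo) + GNLS_MIN_WIDTH))
        elif name == "er":
            out.append((_ER_MIN, er_hi))
        else:  # lga, lla, lb
            out.append((lo, hi))
    return out


def _clip_scale(y: float, series: ConcRespSeries) -> float:
    if series.direction == "gain_only":
        return max(y, 0.0)
    if series.direction == "loss_only":
        return min(y, 0.0)
    return y


def _starts(series: ConcRespSeries, model_id: str) -> list[dict]:
    """Three deterministic, data-derived starting parameter sets."""
    uniq, med, _ = series.groups()
    cmin, cmax = series.conc_range
    lo, hi = math.log10(cmin), math.log10(cmax)
    span = hi - lo
    k = int(np.argmax(np.abs(med)))
    ystar = float(med[k])
    if ystar == 0.0:
        ystar = 1e-3
    ystar = _clip_scale(ystar, series)
    if ystar == 0.0:
        ystar = 1e-3 if series.direction == "gain_only" else -1e-3
    xstar = float(uniq[k])
    # concentration where |median| first reaches half its extreme value
    above = np.flatnonzero(np.abs(med) >= 0.5 * abs(ystar))
    ga_data = float(uniq[above[0]]) if above.size else 10.0 ** (lo + 0.5 * span)
    # residual spread around group medians, for the error-scale start
    resid0 = series.resp - med[np.searchsorted(uniq, series.conc)]
    sd0 = float(np.std(resid0))
    if sd0 <= 0:
        sd0 = max(1e-3, 0.01 * abs(ystar))
    er0 = max(math.log(sd0), _ER_MIN + 1.0)

    grid = [10.0 ** (lo + f * span) for f in (0.3, 0.55, 0.8)]
    starts: list[dict]
    if model_id == "poly1":
        a_lsq = float(np.dot(series.conc, series.resp) / np.dot(series.conc, series.conc))
        a_lsq = _clip_scale(a_lsq, series)
        starts = [{"a": a_lsq}, {"a": ystar / cmax}, {"a": 0.2 * ystar / cmax}]
    elif model_id == "poly2":
        starts = []
        for b in (cmax, grid[1], 5.0 * cmax):
            u = cmax / b
            starts.append({"a": ystar / (u + u * u), "b": b})
    elif model_id == "power":
        starts = [{"a": ystar / cmax**p, "p": p} for p in (0.5, 1.0, 1.5)]
    elif model_id == "hill":
        starts = [
            {"tp": 1.05 * ystar, "ga": ga_data, "p": 1.2},
            {"tp": 1.2 * ystar, "ga": grid[1], "p": 0.8},
            {"tp": ystar, "ga": grid[2], "p": 2.5},
        ]
    elif model_id == "exp4":
        starts = [
            {"tp": 1.05 * ystar, "ga": ga_data},
            {"tp": 1.2 * ystar, "ga": grid[1]},
            {"tp": ystar, "ga": grid[2]},
        ]
    elif model_id == "exp5":
        starts = [
            {"tp": 1.05 * ystar, "ga": ga_data, "p": 1.2},
            {"tp": 1.2 * ystar, "ga": grid[1], "p": 1.0},
            {"tp": ystar, "ga": grid[2], "p": 2.5},
        ]
    elif model_id == "exp2":
        starts = [{"a": ystar / math.expm1(cmax / b), "b": b} for b in (cmax, 0.5 * cmax, 3.0 * cmax)]
    elif model_id == "exp3":
        starts = []
        for b, p in ((cmax, 1.0), (0.5 * cmax, 0.8), (3.0 * cmax, 1.5)):
            starts.append({"a": ystar / math.expm1((cmax / b) ** p), "b": b, "p": p})
    elif model_id == "gnls":
        lpk = math.log10(xstar)
        starts = [
            {"tp": 1.2 * ystar, "ga": 10.0 ** (lpk - 0.75), "p": 1.2,
             "la": 10.0 ** (lpk + 0.75), "q": 1.2},
            {"tp": 1.05 * ystar, "ga": 10.0 ** (lo + 0.2 * span), "p": 2.0,
             "la": 10.0 ** (lo + 0.2 * span + 2.0), "q": 2.0},
            {"tp": ystar, "ga": grid[1], "p": 0.8, "la": grid[1] * 10.0**GNLS_MIN_WIDTH, "q": 0.8},
        ]
    else:
        raise ValueError(f"no starting-value rule for model {model_id!r}")
    for s in starts:
        s["er"] = er0
    return starts


def _clip_to_bounds(vec: np.ndarray, bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.minimum(np.maximum(vec, lo), hi)


def _neg_loglik_factory(
    series: ConcRespSeries,
    model_id: str,
    wnames: Sequence[str],
    scale_fn: Callable[[dict], float | None] | None = None,
) -> Callable[[np.ndarray], float]:
    conc = series.conc
    resp = series.resp

    def nll(vec: np.ndarray) -> float:
        nat = _to_natural(model_id, wnames, vec)
        if scale_fn is not None:
            s = scale_fn(nat)
            if s is None or not np.isfinite(s):
                return 1e10
            nat[MODELS[model_id].scale_param] = s
        with np.errstate(over="ignore", invalid="ignore"):
            pred = _eval_raw(model_id, nat, conc)
        if not np.all(np.isfinite(pred)):
            return 1e10
        val = -t4_loglik(resp - pred, nat["er"])
        return val if np.isfinite(val) else 1e10

    return nll


def _optimize(nll, x0, bounds):
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, jac="3-point",
                   options={"maxiter": 300})
    return res


def fit_one(series: ConcRespSeries, model_id: str) -> ModelFit:
    """Fit a single (non-constant) model to a series.

    Runs the optimizer from three deterministic starting points and keeps
    the best likelihood.  Failure of every attempt is reported through
    ``success=False`` rather than an exception.
    """
    if model_id == "constant":
        return fit_constant(series)
    if model_id not in MODELS:
        raise ValueError(f"unknown model_id: {model_id!r}")
    wnames = _working_names(model_id)
    bounds = _bounds(series, wnames)
    nll = _neg_loglik_factory(series, model_id, wnames)
    best = None
    for start in _starts(series, model_id):
        x0 = _clip_to_bounds(_from_natural(model_id, wnames, start), bounds)
        try:
            res = _optimize(nll, x0, bounds)
        except Exception:  # pragma: no cover - optimizer internals
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    spec = MODELS[model_id]
    if best is None or best.fun >= 1e10:
        nan_params = {n: math.nan for n in spec.param_names}
        nan_params["er"] = math.nan
        return ModelFit(model_id, nan_params, math.nan, math.nan, math.nan,
                        math.nan, math.nan, False, "optimization failed")
    params = _to_natural(model_id, wnames, best.x)
    loglik = -float(best.fun)
    aic = 2.0 * spec.n_params - 2.0 * loglik
    with np.errstate(over="ignore"):
        pred = _eval_raw(model_id, params, series.conc)
    rmse = float(np.sqrt(np.mean((series.resp - pred) ** 2)))
    top, top_conc = model_top(model_id, params, series.conc_range)
    return ModelFit(model_id, params, loglik, aic, rmse, top, top_conc, True)


def fit_constant(series: ConcRespSeries) -> ModelFit:
    """Fit the constant (zero-response) model: only er is estimated."""
    resp = series.resp
    er_hi = math.log(max(float(np.max(np.abs(resp))), 1.0)) + 2.0
    res = minimize_scalar(
        lambda er: -t4_loglik(resp, er), bounds=(_ER_MIN, er_hi), method="bounded",
        options={"xatol": 1e-10},
    )
    loglik = -float(res.fun)
    aic = 2.0 * 1 - 2.0 * loglik
    rmse = float(np.sqrt(np.mean(resp**2)))
    cmax = series.conc_range[1]
    return ModelFit("constant", {"er": float(res.x)}, loglik, aic, rmse, 0.0, cmax, True)


def fit_all(series: ConcRespSeries, cutoff=None) -> WinnerResult:
    """Fit every model family and select the AIC winner.

    Series with fewer than four distinct concentrations return the
    "unable to fit" convention: no fits, winning model None (downstream
    this becomes hitc = 0 with model label "none").  The ``cutoff``
    argument is accepted for pipeline symmetry but does not influence
    fitting or winner selection.
    """
    if series.n_conc < MIN_CONC_FOR_FIT:
        return WinnerResult(None, {}, math.nan)
    fits: dict[str, ModelFit] = {"constant": fit_constant(series)}
    for model_id in FIT_MODELS:
        fits[model_id] = fit_one(series, model_id)
    return WinnerResult(select_winner(fits), fits, fits["constant"].aic)


def select_winner(fits: Mapping[str, ModelFit]) -> str | None:
    """Lowest-AIC successful non-constant model.

    Exact AIC ties go to the model with fewer parameters; any residual
    tie is broken by the fixed :data:`MODEL_PRECEDENCE` order.  Returns
    None when no non-constant fit succeeded (the constant model can
    never win).
    """
    candidates = [f for m, f in fits.items() if m != "constant" and f.success]
    if not candidates:
        return None
    best_aic = min(f.aic for f in candidates)
    tied = [f for f in candidates if f.aic <= best_aic + _AIC_TIE_TOL]
    tied.sort(key=lambda f: (f.n_params, MODEL_PRECEDENCE.index(f.model_id)))
    return tied[0].model_id


def profiled_loglik(
    series: ConcRespSeries,
    model_id: str,
    start_params: Mapping[str, float],
    scale_fn: Callable[[dict], float | None],
    extra_starts: Sequence[Mapping[str, float]] = (),
    return_params: bool = False,
):
    """Maximized log-likelihood with the scale parameter constrained.

    ``scale_fn`` receives the natural shape-parameter dict and must
    return the implied value of the model's scale parameter (``tp`` or
    ``a``) under the constraint being profiled, or None when the
    constraint is infeasible at those shapes.  All remaining shape
    parameters and the error scale are re-optimized from
    ``start_params`` (plus any ``extra_starts``, e.g. warm starts from a
    neighboring profile point).  Used for the top-exceeds-cutoff
    hit-call weight and for benchmark-dose profile intervals.

    With ``return_params`` the maximizing natural parameter dict is
    returned alongside the value.
    """
    spec = MODELS[model_id]
    if spec.scale_param is None:
        raise ValueError("constant model has no scale parameter to profile")
    wnames = _working_names(model_id, skip=spec.scale_param)
    bounds = _bounds(series, wnames)
    nll = _neg_loglik_factory(series, model_id, wnames, scale_fn=scale_fn)
    if len(wnames) == 1:  # only er is free
        res = minimize_scalar(lambda er: nll(np.array([er])), bounds=bounds[0],
                              method="bounded", options={"xatol": 1e-10})
        if return_params:
            return -float(res.fun), {"er": float(res.x)}
        return -float(res.fun)
    best_fun, best_x = math.inf, None
    for start in (start_params, *extra_starts):
        x0 = _clip_to_bounds(_from_natural(model_id, wnames, start), bounds)
        res = _optimize(nll, x0, bounds)
        # a Nelder-Mead polish helps when the constrained surface is kinked
        res2 = minimize(nll, res.x if np.isfinite(res.fun) else x0,
                        method="Nelder-Mead", bounds=bounds,
                        options={"maxiter": 600, "fatol": 1e-10, "xatol": 1e-8})
        for r in (res, res2):
            if float(r.fun) < best_fun:
                best_fun, best_x = float(r.fun), r.x
    if best_fun >= 1e10 or best_x is None:
        return (-math.inf, dict(start_params)) if return_params else -math.inf
    if return_params:
        return -best_fun, _to_natural(model_id, wnames, best_x)
    return -best_fun
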