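"""Parametric concentration-response model functions.

Ten model forms are used to describe the response of an assay endpoint to
a chemical tested over a concentration range (micromolar throughout):

====== ============================================= ==================
model  f(x)                                          shape parameters
====== ============================================= ==================
constant  0                                          (none)
poly1     a*x                                        a
poly2     a*(x/b + (x/b)^2)                          a, b
power     a*x^p                                      a, p
hill      tp / (1 + (ga/x)^p)                        tp, ga, p
gnls      tp / [(1 + (ga/x)^p)(1 + (x/la)^q)]        tp, ga, p, la, q
exp2      a*(exp(x/b) - 1)                           a, b
exp3      a*(exp((x/b)^p) - 1)                       a, b, p
exp4      tp*(1 - 2^(-x/ga))                         tp, ga
exp5      tp*(1 - 2^(-(x/ga)^p))                     tp, ga, p
====== ============================================= ==================

Every model passes through the origin in the limit ``x -> 0+``.  The scale
parameter (``tp`` or ``a``) may take either sign, so a single model family
covers both gain and loss of signal (bidirectional fitting).  Each model
additionally carries an error-scale parameter ``er`` (the log of the
residual scale), counted in ``n_params``.

The gain-loss model ``gnls`` is a Hill gain multiplied by a Hill loss; its
gain and loss AC50s must be separated by at least 1.5 log10 units
(``GNLS_MIN_WIDTH``), which suppresses aberrant single-point "spike" fits
at typical half-log concentration spacing.

All root finding and interior maximization is performed on log10(conc)
for numerical stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "ModelSpec",
    "MODELS",
    "MODEL_IDS",
    "GNLS_MIN_WIDTH",
    "evaluate",
    "model_top",
    "inverse_conc",
]

#: minimum separation, in log10 units, between the gnls loss and gain AC50s
GNLS_MIN_WIDTH = 1.5


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one model family.

    ``param_names`` lists the shape parameters in canonical order (the
    error scale ``er`` is implicit); ``scale_param`` names the parameter
    the response is linear in (``None`` for the constant model);
    ``monotone`` is True when |f| is non-decreasing in concentration for
    any admissible parameter values.
    """

    model_id: str
    param_names: tuple[str, ...]
    scale_param: str | None
    monotone: bool

    @property
    def n_params(self) -> int:
        """Number of fitted parameters, including the error scale er."""
        return len(self.param_names) + 1


MODELS: dict[str, ModelSpec] = {
    "constant": ModelSpec("constant", (), None, True),
    "poly1": ModelSpec("poly1", ("a",), "a", True),
    "poly2": ModelSpec("poly2", ("a", "b"), "a", True),
    "power": ModelSpec("power", ("a", "p"), "a", True),
    "hill": ModelSpec("hill", ("tp", "ga", "p"), "tp", True),
    "gnls": ModelSpec("gnls", ("tp", "ga", "p", "la", "q"), "tp", False),
    "exp2": ModelSpec("exp2", ("a", "b"), "a", True),
    "exp3": ModelSpec("exp3", ("a", "b", "p"), "a", True),
    "exp4": ModelSpec("exp4", ("tp", "ga"), "tp", True),
    "exp5": ModelSpec("exp5", ("tp", "ga", "p"), "tp", True),
}

MODEL_IDS: tuple[str, ...] = tuple(MODELS)

_POSITIVE_PARAMS = ("ga", "la", "b", "p", "q")


def _check_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id: {model_id!r}") from None


def _validate_params(spec: ModelSpec, params: Mapping[str, float]) -> None:
    for name in spec.param_names:
        if name not in params:
            raise ValueError(f"model {spec.model_id!r} requires parameter {name!r}")
        if name in _POSITIVE_PARAMS and not params[name] > 0:
            raise ValueError(f"parameter {name!r} must be > 0, got {params[name]}")
    if spec.model_id == "gnls":
        width = math.log10(params["la"]) - math.log10(params["ga"])
        if width < GNLS_MIN_WIDTH - 1e-9:
            raise ValueError(
                f"gnls requires log10(la) - log10(ga) >= {GNLS_MIN_WIDTH}, got {width:.4f}"
            )


def evaluate(model_id: str, params: Mapping[str, float], conc):
    """Evaluate a model at one or more (strictly positive) concentrations.

    Parameters
    ----------
    model_id
        One of :data:`MODEL_IDS`.
    params
        Mapping holding the shape parameters the model requires (``er``
        is ignored here).
    conc
        Scalar or array of concentrations in µM, all > 0.

    Returns
    -------
    Response value(s) with the same shape as ``conc``.
    """
    spec = _check_model(model_id)
    _validate_params(spec, params)
    x = np.asarray(conc, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    with np.errstate(over="ignore"):  # saturating curves may overflow to inf
        y = _eval_raw(model_id, params, x)
    return float(y[0]) if scalar else y


def _eval_raw(model_id: str, p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    """Model equations without validation; x is a positive float array."""
    if model_id == "constant":
        return np.zeros_like(x)
    if model_id == "poly1":
        return p["a"] * x
    if model_id == "poly2":
        u = x / p["b"]
        return p["a"] * (u + u * u)
    if model_id == "power":
        return p["a"] * np.power(x, p["p"])
    if model_id == "hill":
        return p["tp"] / (1.0 + np.power(p["ga"] / x, p["p"]))
    if model_id == "gnls":
        gain = 1.0 + np.power(p["ga"] / x, p["p"])
        loss = 1.0 + np.power(x / p["la"], p["q"])
        return p["tp"] / (gain * loss)
    if model_id == "exp2":
        return p["a"] * np.expm1(x / p["b"])
    if model_id == "exp3":
        return p["a"] * np.expm1(np.power(x / p["b"], p["p"]))
    if model_id == "exp4":
        return p["tp"] * (1.0 - np.exp2(-x / p["ga"]))
    if model_id == "exp5":
        return p["tp"] * (1.0 - np.exp2(-np.power(x / p["ga"], p["p"])))
    raise ValueError(f"unknown model_id: {model_id!r}")


def model_top(
    model_id: str, params: Mapping[str, float], conc_range: tuple[float, float]
) -> tuple[float, float]:
    """Signed modeled top over a concentration window.

    Returns ``(top, top_conc)`` where ``top`` is the model response of
    maximal absolute value over ``[cmin, cmax]`` and ``top_conc`` the
    concentration attaining it.  For monotone models the top sits at
    ``cmax``; for gnls the interior maximum is located numerically
    (100-point log grid followed by golden-section refinement on
    log10(conc)).
    """
    spec = _check_model(model_id)
    cmin, cmax = float(conc_range[0]), float(conc_range[1])
    if not (0 < cmin < cmax):
        raise ValueError("conc_range must satisfy 0 < cmin < cmax")
    if spec.model_id == "constant":
        return 0.0, cmax
    if spec.monotone:
        return evaluate(model_id, params, cmax), cmax
    # gnls: |f| is unimodal in log-conc; seed with a grid then refine
    _validate_params(spec, params)
    lo, hi = math.log10(cmin), math.log10(cmax)
    grid = np.logspace(lo, hi, 100)
    vals = _eval_raw(model_id, params, grid)
    k = int(np.argmax(np.abs(vals)))
    a = math.log10(grid[max(k - 1, 0)])
    b = math.log10(grid[min(k + 1, len(grid) - 1)])
    if a == b:
        return float(vals[k]), float(grid[k])
    res = minimize_scalar(
        lambda lx: -abs(float(_eval_raw(model_id, params, np.array([10.0**lx]))[0])),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    top_conc = 10.0 ** float(res.x)
    top = float(_eval_raw(model_id, params, np.array([top_conc]))[0])
    if abs(top) < abs(vals[k]):  # guard against a failed refinement
        return float(vals[k]), float(grid[k])
    return top, top_conc


def inverse_conc(
    model_id: str,
    params: Mapping[str, float],
    target_response: float,
    conc_range: tuple[float, float],
    n_grid: int = 512,
) -> float | None:
    """Smallest concentration in ``conc_range`` where f equals a target.

    The crossing is located on a log10-spaced grid and refined with
    Brent's method in log10(conc) space.  Returns ``None`` when the
    target level is never attained inside the window (this includes a
    target whose magnitude exceeds the modeled top — absence, not an
    exception).  A target of the wrong sign relative to the curve is
    likewise never attained.
    """
    spec = _check_model(model_id)
    _validate_params(spec, params)
    cmin, cmax = float(conc_range[0]), float(conc_range[1])
    if not (0 < cmin < cmax):
        raise ValueError("conc_range must satisfy 0 < cmin < cmax")
    t = float(target_response)
    if t == 0.0 or not math.isfinite(t) or spec.model_id == "constant":
        return None
    grid = np.logspace(math.log10(cmin), math.log10(cmax), n_grid)
    with np.errstate(over="ignore", invalid="ignore"):
        h = _eval_raw(model_id, params, grid) - t
    exact = np.flatnonzero(h == 0.0)
    sign_change = np.flatnonzero(np.sign(h[:-1]) * np.sign(h[1:]) < 0)
    first_exact = exact[0] if exact.size else np.inf
    first_cross = sign_change[0] if sign_change.size else np.inf
    if first_exact <= first_cross:
        if not np.isfinite(first_exact):
            return None
        return float(grid[int(first_exact)])
    i = int(first_cross)

    def g(lx: float) -> float:
        return float(_eval_raw(model_id, params, np.array([10.0**lx]))[0]) - t

    lx = brentq(g, math.log10(grid[i]), math.log10(grid[i + 1]), xtol=1e-12)
    return float(10.0**lx)
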