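"""Pipeline orchestration: normalized series table in, long tables out.

Drives the full per-series chain — model fitting and winner selection,
continuous hit call, potency set, fit category, cautionary flags — over
a long-format level-3-style input table and assembles long-format output
tables mirroring the conventional level 4-6 layout:

``mc4``        one summary row per (series, model): AIC, RMSE, top, ...
``mc4_param``  one row per fitted model parameter (long format)
``mc5``        one row per series: winner, hitc, cutoff, fit category
``mc5_param``  one row per hit-call weight / potency metric (long format)
``mc6``        one row per raised cautionary flag

Every row carries a stable series identifier ``m4id`` assigned in input
order.  Per-series failures are recorded in the run log and never abort
the run.  Concentrations are µM end to end.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import pandas as pd
import yaml

from .baseline import CutoffSpec, compute_cutoff_spec
from .fitcat import assign_fitc
from .fitting import ConcRespSeries, fit_all
from .flags import FLAG_DESCRIPTIONS, EndpointMeta, apply_flags
from .hitcall import DEFAULT_HIT_THRESHOLD, continuous_hitcall
from .potency import ACXX_LEVELS, bmd_bounds, compute_potencies

__all__ = ["EndpointConfig", "RunConfig", "load_config", "run_pipeline", "write_outputs"]

_MC3_COLUMNS = ("aeid", "spid", "conc", "resp")


@dataclass(frozen=True)
class EndpointConfig:
    """Method assignment for one endpoint."""

    bmad_method: str = "lowconc_twells"
    cutoff_methods: tuple[str, ...] = ("bmad3",)
    direction: str = "bidirectional"
    scale: str = "percent"
    cell_viability: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Run-wide processing decisions.

    ``endpoints`` maps endpoint ids to per-endpoint overrides of the
    defaults; any endpoint absent from the map inherits ``defaults``.
    The configuration is echoed verbatim into the run log so every
    processing decision is traceable.
    """

    defaults: EndpointConfig = EndpointConfig()
    endpoints: dict = field(default_factory=dict)
    hitc_threshold: float = DEFAULT_HIT_THRESHOLD
    w_median_dialect: str = "v4.1_median"
    compute_bmd_bounds: bool = False
    seed: int = 0

    def for_endpoint(self, aeid: str) -> EndpointConfig:
        overrides = self.endpoints.get(aeid, {})
        if isinstance(overrides, EndpointConfig):
            return overrides
        cfg = replace(self.defaults, **overrides)
        return cfg


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    defaults = EndpointConfig(**{
        **raw.get("defaults", {}),
        **({"cutoff_methods": tuple(raw["defaults"]["cutoff_methods"])}
           if "cutoff_methods" in raw.get("defaults", {}) else {}),
    })
    endpoints = {}
    for aeid, over in (raw.get("endpoints") or {}).items():
        over = dict(over)
        if "cutoff_methods" in over:
            over["cutoff_methods"] = tuple(over["cutoff_methods"])
        endpoints[str(aeid)] = over
    return RunConfig(
        defaults=defaults,
        endpoints=endpoints,
        hitc_threshold=float(raw.get("hitc_threshold", DEFAULT_HIT_THRESHOLD)),
        w_median_dialect=str(raw.get("w_median_dialect", "v4.1_median")),
        compute_bmd_bounds=bool(raw.get("compute_bmd_bounds", False)),
        seed=int(raw.get("seed", 0)),
    )


def _validate_mc3(mc3: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _MC3_COLUMNS if c not in mc3.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")
    bad = mc3["conc"].le(0) | ~mc3["conc"].apply(math.isfinite) | ~mc3["resp"].apply(math.isfinite)
    if bad.any():
        raise ValueError(
            f"malformed input rows (non-positive conc or non-finite values) at "
            f"index {list(mc3.index[bad])[:10]}"
        )
    return mc3


def run_pipeline(mc3: pd.DataFrame, config: RunConfig = RunConfig()):
    """Process a level-3-style table through fitting, hit calling,
    potency, categorization, and flagging.

    Returns ``(tables, log)`` where tables is a dict with keys mc4,
    mc4_param, mc5, mc5_param, mc6 and log a list of run-log lines.
    """
    mc3 = _validate_mc3(mc3)
    log: list[str] = [f"run config: {config}"]
    mc4_rows, mc4p_rows, mc5_rows, mc5p_rows, mc6_rows = [], [], [], [], []
    m4id = 0
    for aeid, etable in mc3.groupby("aeid", sort=False):
        ecfg = config.for_endpoint(str(aeid))
        try:
            cutoff = compute_cutoff_spec(etable, ecfg.bmad_method, ecfg.cutoff_methods)
        except ValueError as exc:
            log.append(f"endpoint {aeid}: SKIPPED ({exc})")
            continue
        log.append(
            f"endpoint {aeid}: bmad_method={ecfg.bmad_method} "
            f"cutoff_methods={list(ecfg.cutoff_methods)} direction={ecfg.direction} "
            f"bmad={cutoff.bmad:.6g} onesd={cutoff.onesd:.6g} bmr={cutoff.bmr:.6g} "
            f"coff={cutoff.coff:.6g}"
        )
        meta = EndpointMeta(scale=ecfg.scale, cell_viability=ecfg.cell_viability)
        treated = etable[etable["wllt"].eq("t")] if "wllt" in etable.columns else etable
        for spid, stable in treated.groupby("spid", sort=False):
            m4id += 1
            try:
                _process_series(
                    m4id, str(aeid), str(spid), stable, ecfg, cutoff, meta, config,
                    mc4_rows, mc4p_rows, mc5_rows, mc5p_rows, mc6_rows,
                )
            except Exception as exc:  # never abort the run on one series
                log.append(f"series {aeid}/{spid} (m4id={m4id}): FAILED ({exc})")
    tables = {
        "mc4": pd.DataFrame(
            mc4_rows,
            columns=["m4id", "aeid", "spid", "model", "success", "loglik", "aic",
                     "rmse", "top", "top_conc"],
        ),
        "mc4_param": pd.DataFrame(
            mc4p_rows, columns=["m4id", "aeid", "spid", "model", "model_param", "model_val"]
        ),
        "mc5": pd.DataFrame(
            mc5_rows,
            columns=["m4id", "aeid", "spid", "modl", "hitc", "active", "fitc",
                     "fitc_label", "coff", "bmad", "onesd", "bmr", "top", "ac50", "bmd"],
        ),
        "mc5_param": pd.DataFrame(
            mc5p_rows, columns=["m4id", "aeid", "spid", "hit_param", "hit_val"]
        ),
        "mc6": pd.DataFrame(
            mc6_rows, columns=["m4id", "aeid", "spid", "flag", "flag_description"]
        ),
    }
    return tables, log


def _process_series(m4id, aeid, spid, stable, ecfg, cutoff, meta, config,
                    mc4_rows, mc4p_rows, mc5_rows, mc5p_rows, mc6_rows) -> None:
    series = ConcRespSeries(
        spid, aeid, stable["conc"].to_numpy(float), stable["resp"].to_numpy(float),
        direction=ecfg.direction,
    )
    winner = fit_all(series, cutoff)
    hit = continuous_hitcall(series, winner, cutoff, dialect=config.w_median_dialect,
                             threshold=config.hitc_threshold)
    fit = winner.winner
    potency = compute_potencies(fit, cutoff, series.conc_range)
    if config.compute_bmd_bounds and fit is not None and potency.bmd is not None:
        bmdl, bmdu = bmd_bounds(series, fit, cutoff.bmr)
        potency = replace(potency, bmdl=bmdl, bmdu=bmdu)
    fitc = assign_fitc(hit, fit, potency, cutoff, series.conc_range,
                       threshold=config.hitc_threshold)
    flags = apply_flags(series, fit, hit, potency, cutoff, meta)

    for model_id, mfit in winner.fits.items():
        mc4_rows.append((m4id, aeid, spid, model_id, mfit.success, mfit.loglik,
                         mfit.aic, mfit.rmse, mfit.top, mfit.top_conc))
        for name, val in mfit.params.items():
            mc4p_rows.append((m4id, aeid, spid, model_id, name, val))

    modl = winner.winning_model if winner.winning_model is not None else "none"
    mc5_rows.append((
        m4id, aeid, spid, modl, hit.hitc, hit.active, fitc.code, fitc.label,
        cutoff.coff, cutoff.bmad, cutoff.onesd, cutoff.bmr,
        fit.top if fit is not None else math.nan,
        potency.ac50 if potency.ac50 is not None else math.nan,
        potency.bmd if potency.bmd is not None else math.nan,
    ))
    hit_params = {
        "hitc": hit.hitc, "w_aic": hit.w_aic, "w_median": hit.w_median,
        "w_top": hit.w_top, "coff": cutoff.coff, "bmr": cutoff.bmr,
    }
    for name in (*ACXX_LEVELS, "acb", "acc", "bmd", "bmdl", "bmdu"):
        val = getattr(potency, name)
        if val is not None:
            hit_params[name] = val
    for name, val in hit_params.items():
        mc5p_rows.append((m4id, aeid, spid, name, val))
    for flag in sorted(flags):
        mc6_rows.append((m4id, aeid, spid, flag, FLAG_DESCRIPTIONS[flag]))


def write_outputs(tables: dict, log: list, outdir) -> None:
    """Write the five long-format CSVs plus the run log."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
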