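"""Baseline variability estimation and efficacy cutoffs.

An endpoint's baseline noise is summarized two ways:

* **BMAD** — the scaled median absolute deviation (consistency constant
  1.4826) of responses in wells that represent baseline, pooled across
  every sample of the endpoint.  Baseline wells are either the treatment
  wells at the two lowest concentration indices (``lowconc_twells``, the
  default) or wells labeled as neutral controls (``neutral_ctrl``).
* **onesd** — the pooled sample standard deviation of responses at the
  two lowest concentration indices, from which the benchmark response is
  derived as BMR = 1.349 * onesd.

The efficacy cutoff ``coff`` is the maximum over the candidate values
produced by the cutoff methods assigned to the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutoffSpec",
    "BMR_MULTIPLIER",
    "MAD_CONSISTENCY",
    "CUTOFF_METHODS",
    "compute_bmad",
    "compute_onesd",
    "compute_cutoff",
    "compute_cutoff_spec",
]

#: multiplier mapping baseline SD to the benchmark response
BMR_MULTIPLIER = 1.349
#: scaled-MAD consistency constant (makes MAD estimate sigma for a normal)
MAD_CONSISTENCY = 1.4826

#: cutoff methods: name -> candidate cutoff as a function of bmad.
#: ``bmad3`` is 3*BMAD; ``pc20`` a 20% change on percent-scale endpoints;
#: ``fc1.2`` a 1.2-fold change, i.e. log2(1.2), on log2 fold-change
#: endpoints (the unit dialect is declared by the endpoint's scale).
CUTOFF_METHODS = {
    "bmad3": lambda bmad: 3.0 * bmad,
    "pc20": lambda bmad: 20.0,
    "fc1.2": lambda bmad: float(np.log2(1.2)),
}


@dataclass(frozen=True)
class CutoffSpec:
    """Baseline summary and efficacy cutoff for one endpoint.

    bmr is always 1.349 * onesd; coff is the max over the candidates of
    the assigned cutoff methods and is strictly positive.
    """

    bmad: float
    onesd: float
    coff: float
    bmad_method: str = "lowconc_twells"
    cutoff_methods: tuple[str, ...] = ("bmad3",)

    @property
    def bmr(self) -> float:
        return BMR_MULTIPLIER * self.onesd

    def __post_init__(self) -> None:
        if self.bmad < 0 or self.onesd < 0:
            raise ValueError("bmad and onesd must be non-negative")
        if not self.coff > 0:
            raise ValueError("coff must be strictly positive")


def _baseline_responses(table: pd.DataFrame, method: str) -> np.ndarray:
    if method == "lowconc_twells":
        mask = table["wllt"].eq("t") if "wllt" in table.columns else np.ones(len(table), bool)
        treated = table.loc[mask]
        concs = np.sort(treated["conc"].unique())
        if concs.size < 2:
            raise ValueError(
                "baseline estimation needs at least two distinct concentration indices"
            )
        return treated.loc[treated["conc"].isin(concs[:2]), "resp"].to_numpy(float)
    if method == "neutral_ctrl":
        if "wllt" not in table.columns:
            raise ValueError("neutral_ctrl baseline requires a 'wllt' column")
        resp = table.loc[table["wllt"].eq("n"), "resp"].to_numpy(float)
        if resp.size == 0:
            raise ValueError("no neutral-control wells found for this endpoint")
        return resp
    raise ValueError(f"unknown bmad method: {method!r}")


def compute_bmad(table: pd.DataFrame, method: str = "lowconc_twells") -> float:
    """Scaled MAD of baseline-representative responses for one endpoint.

    ``table`` is a long-format response table with columns ``conc``,
    ``resp`` and optionally ``wllt`` (well type: 't' treatment, 'n'
    neutral control), pooled over all samples of the endpoint.
    """
    resp = _baseline_responses(table, method)
    if resp.size == 0:
        raise ValueError("empty baseline selection; endpoint cannot be configured")
    med = np.median(resp)
    return float(MAD_CONSISTENCY * np.median(np.abs(resp - med)))


def compute_onesd(table: pd.DataFrame) -> float:
    """Pooled sample SD at the two lowest concentration indices.

    This is the baseline spread that defines the benchmark response
    (BMR = 1.349 * onesd).  Requires at least two baseline observations.
    """
    resp = _baseline_responses(table, "lowconc_twells")
    if resp.size < 2:
        raise ValueError("onesd requires at least two baseline observations")
    return float(np.std(resp, ddof=1))


def compute_cutoff(cutoff_methods: Sequence[str] | Iterable[str], bmad: float) -> float:
    """Efficacy cutoff: the maximum candidate over the assigned methods."""
    methods = list(cutoff_methods)
    if not methods:
        raise ValueError("at least one cutoff method must be assigned")
    candidates = []
    for name in methods:
        if name not in CUTOFF_METHODS:
            raise ValueError(f"unknown cutoff method: {name!r}")
        candidates.append(CUTOFF_METHODS[name](bmad))
    return float(max(candidates))


def compute_cutoff_spec(
    table: pd.DataFrame,
    bmad_method: str = "lowconc_twells",
    cutoff_methods: Sequence[str] = ("bmad3",),
) -> CutoffSpec:
    """Convenience wrapper: BMAD + onesd + cutoff for one endpoint table."""
    bmad = compute_bmad(table, bmad_method)
    onesd = compute_onesd(table)
    coff = compute_cutoff(cutoff_methods, bmad)
    return CutoffSpec(
        bmad=bmad,
        onesd=onesd,
        coff=coff,
        bmad_method=bmad_method,
        cutoff_methods=tuple(cutoff_methods),
    )
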