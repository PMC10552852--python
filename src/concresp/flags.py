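"""Cautionary flags on curve behavior.

Flags are programmatic annotations attached to each fitted series that
point a reviewer at curves needing extra scrutiny — borderline efficacy,
single-concentration activity, noisy data, questionable directionality,
and so on.  They never alter the hit call or any potency estimate.

Each flag is evaluated independently; "baseline" for the single-point
flags means the default baseline region boundary, 3*BMAD.  Flags whose
inputs are absent (e.g. bmd.high without a BMD) are simply not raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .baseline import CutoffSpec
from .fitting import ConcRespSeries, ModelFit
from .hitcall import HitResult
from .potency import PotencySet

__all__ = ["EndpointMeta", "FLAG_DESCRIPTIONS", "apply_flags"]

FLAG_DESCRIPTIONS: dict[str, str] = {
    "modl.directionality.fail": (
        "Model directionality is questionable as data points are split in "
        "positive and negative axis"
    ),
    "low.nrep": "Average number of replicates per conc is less than 2",
    "low.nconc": "Number of concentrations tested is less than 4",
    "bmd.high": "Bmd > ac50, indication of high baseline variability",
    "singlept.hit.high": "Only highest conc above baseline, active",
    "singlept.hit.mid": "Only one conc above baseline, active",
    "multipoint.neg": "Multiple points above baseline, inactive",
    "gnls.lowconc": (
        "Complete gain-loss curve not within concentration range tested: gain "
        "AC50 below the lowest tested concentration or loss AC50 above the "
        "mean tested concentration"
    ),
    "noise": "Noisy data (rmse > coff)",
    "border": "Borderline activity (0.8*coff <= |top| <= 1.2*coff)",
    "efficacy.50": "Less than 50% efficacy",
    "ac50.lowconc": "AC50 less than lowest concentration tested",
    "viability.gnls": "Cell viability assay fit with gain-loss winning model",
}


@dataclass(frozen=True)
class EndpointMeta:
    """Endpoint annotations the flags depend on.

    ``scale`` declares the response-unit dialect ("percent" or "log2");
    it selects the 50%-efficacy threshold (50 response units on percent
    scales, log2(1.5) on log2 fold-change scales).
    """

    scale: str = "percent"
    cell_viability: bool = False


def _efficacy50_threshold(meta: EndpointMeta) -> float:
    if meta.scale == "log2":
        return math.log2(1.5)
    return 50.0


def apply_flags(
    series: ConcRespSeries,
    winner_fit: ModelFit | None,
    hit: HitResult,
    potency: PotencySet,
    cutoff: CutoffSpec,
    endpoint_meta: EndpointMeta = EndpointMeta(),
) -> frozenset:
    """Evaluate every cautionary flag for one pipeline record.

    Pure function of its inputs: the same record always yields the same
    flag set.  Returns the set of raised flag names (see
    :data:`FLAG_DESCRIPTIONS`).
    """
    flags: set[str] = set()
    uniq, med, cnt = series.groups()
    coff = cutoff.coff
    baseline = 3.0 * cutoff.bmad
    cmin = float(uniq[0])

    if float(np.mean(cnt)) < 2.0:
        flags.add("low.nrep")
    if uniq.size < 4:
        flags.add("low.nconc")
    if np.any(med > 0.5 * coff) and np.any(med < -0.5 * coff):
        flags.add("modl.directionality.fail")

    above = np.abs(med) > baseline if baseline > 0 else np.zeros(uniq.size, bool)
    n_above = int(above.sum())
    if hit.active:
        if n_above == 1 and above[-1]:
            flags.add("singlept.hit.high")
        elif n_above == 1:
            flags.add("singlept.hit.mid")
    else:
        if n_above >= 2:
            flags.add("multipoint.neg")

    if winner_fit is not None and winner_fit.success:
        top = abs(winner_fit.top)
        if winner_fit.rmse > coff:
            flags.add("noise")
        if 0.8 * coff <= top <= 1.2 * coff:
            flags.add("border")
        if top < _efficacy50_threshold(endpoint_meta):
            flags.add("efficacy.50")
        if winner_fit.model_id == "gnls":
            ga = winner_fit.params["ga"]
            la = winner_fit.params["la"]
            if ga < cmin or la > float(np.mean(uniq)):
                flags.add("gnls.lowconc")
            if endpoint_meta.cell_viability:
                flags.add("viability.gnls")

    if potency.bmd is not None and potency.ac50 is not None and potency.bmd > potency.ac50:
        flags.add("bmd.high")
    if potency.ac50 is not None and potency.ac50 < cmin:
        flags.add("ac50.lowconc")

    return frozenset(flags)
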