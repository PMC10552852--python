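"""Fit-category assignment.

Every processed curve is placed in exactly one leaf of a hierarchical
tree.  Curves are first split into cannot-determine (no winning model,
e.g. fewer than four tested concentrations), inactive (hitc below the
activity threshold), or active.  Inactive curves are split on whether
the modeled |top| approaches the cutoff (|top| >= 0.8*coff indicates
borderline inactivity).  Active curves are split on efficacy
(|top| <= 1.2*coff: borderline; otherwise moderate) and then placed by
where their potency estimates sit relative to the tested concentration
range:

========  ==========  =========================================
code      efficacy    potency placement
========  ==========  =========================================
36 / 40   <=1.2 / >   AC50 at or below the lowest tested conc
37 / 41   <=1.2 / >   AC50 and AC95 inside the tested range
38 / 42   <=1.2 / >   AC95 at or beyond the highest tested conc
========  ==========  =========================================

Codes 37/41 mark the most quantitatively informative AC50 values; 36/40
AC50s sit below the screened range and 38/42 curves may not have reached
maximal activity within it.  The 36-42 codes are fixed by convention;
the cannot-determine and inactive leaves carry configurable codes (2,
13, 15) with the symbolic labels authoritative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .baseline import CutoffSpec
from .fitting import ModelFit
from .hitcall import HitResult
from .potency import PotencySet

__all__ = ["FitCategory", "FIT_CATEGORIES", "assign_fitc", "fit_category_table"]


@dataclass(frozen=True)
class FitCategory:
    code: int
    label: str


FIT_CATEGORIES: dict[str, int] = {
    "cannot_determine": 2,
    "inactive_clear": 13,
    "inactive_borderline": 15,
    "active_borderline_ac50_below": 36,
    "active_borderline_informative": 37,
    "active_borderline_ac95_above": 38,
    "active_moderate_ac50_below": 40,
    "active_moderate_informative": 41,
    "active_moderate_ac95_above": 42,
}


def _category(label: str) -> FitCategory:
    return FitCategory(FIT_CATEGORIES[label], label)


def assign_fitc(
    hit: HitResult,
    winner_fit: ModelFit | None,
    potency: PotencySet,
    cutoff: CutoffSpec,
    conc_range: tuple[float, float],
    threshold: float = 0.90,
) -> FitCategory:
    """Walk the fit-category tree for one pipeline record.

    The efficacy comparisons use the modeled top within the tested
    range in absolute value, so the category is invariant under a
    response sign flip.  An active record with an absent AC50 is
    inconsistent and raises.
    """
    if winner_fit is None or not winner_fit.success:
        return _category("cannot_determine")
    coff = cutoff.coff
    top = abs(winner_fit.top)
    if hit.hitc < threshold:
        if top < 0.8 * coff:
            return _category("inactive_clear")
        return _category("inactive_borderline")
    # active branch
    if potency.ac50 is None:
        raise ValueError("active series with absent AC50: inconsistent inputs")
    cmin, cmax = conc_range
    band = "borderline" if top <= 1.2 * coff else "moderate"
    if potency.ac50 <= cmin:
        placement = "ac50_below"
    elif potency.ac95 is None or potency.ac95 >= cmax:
        placement = "ac95_above"
    else:
        placement = "informative"
    return _category(f"active_{band}_{placement}")


def fit_category_table() -> list[dict]:
    """The shipped fit-category lookup (code, label, description rows)."""
    with resources.files("concresp.data").joinpath("fit_categories.csv").open() as fh:
        return list(csv.DictReader(fh))
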