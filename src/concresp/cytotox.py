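"""Cytotoxicity "burst" threshold computation.

Many cell-based stress and viability endpoints activate together near a
chemical's cytotoxic concentration — the "burst".  Given a chemical x
burst-endpoint table of hit calls and AC50s, this module derives, per
chemical:

* ``cyto_pt`` — the burst point, the median log10(AC50) over the
  chemical's active burst endpoints, requiring a minimum number of
  endpoints before reporting anything other than the default of
  1000 µM (3 on the log10-µM scale);
* ``lower_bound`` — ``cyto_pt - 3 * global_mad``, where the global MAD
  is the median over well-tested chemicals (at least 60 burst endpoints
  tested, active hit rate above 5%) of the scaled MAD of their active
  log10(AC50) values.

Before any computation the table is filtered: gain-loss (gnls) winning
fits and cell-proliferation (gain-direction) responses are removed so
only genuine losses in viability contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import MAD_CONSISTENCY

__all__ = [
    "DEFAULT_CYTO_PT_LOG10",
    "BurstResult",
    "filter_burst",
    "chemical_burst_point",
    "global_mad",
    "lower_bound",
    "burst_summary",
]

#: default burst point for insufficiently tested chemicals: log10(1000 µM)
DEFAULT_CYTO_PT_LOG10 = 3.0

_REQUIRED_COLUMNS = ("chemical_id", "endpoint_id", "tested", "active", "ac50")


@dataclass(frozen=True)
class BurstResult:
    """Per-chemical burst summary (concentrations in log10-µM)."""

    chemical_id: str
    cyto_pt: float
    n_tested: int
    n_active: int
    used_default: bool
    global_mad: float
    lower_bound: float


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"burst table is missing columns: {missing}")


def filter_burst(table: pd.DataFrame) -> pd.DataFrame:
    """Drop gain-loss fits and proliferation-direction rows.

    Expects optional ``winning_model`` and ``proliferation_direction``
    columns; rows failing either filter are removed so that only losses
    in cell viability feed the burst computation.
    """
    _validate(table)
    out = table
    if "winning_model" in out.columns:
        out = out[out["winning_model"].ne("gnls")]
    if "proliferation_direction" in out.columns:
        out = out[~out["proliferation_direction"].astype(bool)]
    return out.reset_index(drop=True)


def chemical_burst_point(
    rows: pd.DataFrame, min_active: int = 3, min_tested: int = 3
) -> tuple[float, bool]:
    """Burst point for one chemical from its filtered burst rows.

    Returns ``(cyto_pt, used_default)`` with cyto_pt in log10-µM.  The
    default (log10 of 1000 µM) is reported unless the chemical was
    tested in at least ``min_tested`` endpoints and active in at least
    ``min_active`` of them; the median is taken over the active rows'
    log10(AC50) values.
    """
    _validate(rows)
    tested = rows[rows["tested"].astype(bool)]
    active = tested[tested["active"].astype(bool)]
    if len(tested) < min_tested or len(active) < min_active:
        return DEFAULT_CYTO_PT_LOG10, True
    return float(np.median(np.log10(active["ac50"].to_numpy(float)))), False


def global_mad(
    table: pd.DataFrame, min_tested: int = 60, min_hit_rate: float = 0.05
) -> float:
    """Global burst variability (log10-µM) over qualifying chemicals.

    For each chemical tested in at least ``min_tested`` burst endpoints
    with an active hit rate above ``min_hit_rate``, the scaled MAD of
    its active log10(AC50) values is computed; the global MAD is the
    median of these per-chemical values.  Raises if no chemical
    qualifies (the burst set is unusable).
    """
    _validate(table)
    mads = []
    for _, rows in table.groupby("chemical_id"):
        tested = rows[rows["tested"].astype(bool)]
        active = tested[tested["active"].astype(bool)]
        n_tested = len(tested)
        if n_tested < min_tested or len(active) / max(n_tested, 1) <= min_hit_rate:
            continue
        log_ac50 = np.log10(active["ac50"].to_numpy(float))
        med = np.median(log_ac50)
        mads.append(MAD_CONSISTENCY * float(np.median(np.abs(log_ac50 - med))))
    if not mads:
        raise ValueError("no chemical qualifies for the global MAD computation")
    return float(np.median(mads))


def lower_bound(cyto_pt: float, gmad: float) -> float:
    """Burst lower bound: chemical median minus three global MADs."""
    return cyto_pt - 3.0 * gmad


def burst_summary(
    table: pd.DataFrame,
    min_active: int = 3,
    min_tested: int = 3,
    mad_min_tested: int = 60,
    mad_min_hit_rate: float = 0.05,
) -> pd.DataFrame:
    """Full burst computation: filter, per-chemical points, global MAD.

    Returns one row per chemical with cyto_pt, lower_bound (log10-µM),
    cyto_pt_um, counts, and the shared global MAD.
    """
    filtered = filter_burst(table)
    gmad = global_mad(filtered, min_tested=mad_min_tested, min_hit_rate=mad_min_hit_rate)
    records = []
    for chem, rows in filtered.groupby("chemical_id", sort=True):
        pt, used_default = chemical_burst_point(rows, min_active=min_active, min_tested=min_tested)
        tested = rows[rows["tested"].astype(bool)]
        records.append(
            BurstResult(
                chemical_id=str(chem),
                cyto_pt=pt,
                n_tested=len(tested),
                n_active=int(tested["active"].astype(bool).sum()),
                used_default=used_default,
                global_mad=gmad,
                lower_bound=lower_bound(pt, gmad),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    df["cyto_pt_um"] = 10.0 ** df["cyto_pt"]
    return df
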