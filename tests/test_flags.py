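"""Cautionary flags: triggers, exclusivity, purity."""

import numpy as np
import pytest

from concresp.baseline import CutoffSpec
from concresp.fitting import ModelFit
from concresp.flags import FLAG_DESCRIPTIONS, EndpointMeta, apply_flags
from concresp.hitcall import HitResult
from concresp.potency import PotencySet
from tests.conftest import make_series

CUT = CutoffSpec(bmad=2.0, onesd=2.0, coff=10.0)  # baseline boundary 3*bmad = 6


def _series(medians, n_rep=3, conc0=0.1):
    conc = conc0 * 10 ** (0.5 * np.arange(len(medians)))
    return make_series(np.repeat(conc, n_rep), np.repeat(medians, n_rep))


def _fit(top=20.0, model_id="hill", rmse=1.0, params=None):
    params = params or {"tp": top, "ga": 1.0, "p": 2.0, "er": 0.0}
    return ModelFit(model_id, params, 0.0, 0.0, rmse, top, 10.0, True)


ACTIVE = HitResult(0.95, 1, 1, 0.95, True)
INACTIVE = HitResult(0.2, 1, 1, 0.2, False)


def test_bmd_above_ac50_flagged():
    flags = apply_flags(_series([0, 0, 0, 30]), _fit(), ACTIVE,
                        PotencySet(ac50=2.0, bmd=5.0), CUT)
    assert "bmd.high" in flags
    flags = apply_flags(_series([0, 0, 0, 30]), _fit(), ACTIVE,
                        PotencySet(ac50=5.0, bmd=2.0), CUT)
    assert "bmd.high" not in flags


def test_low_nconc_and_low_nrep():
    flags = apply_flags(_series([0, 0, 30], n_rep=1), _fit(), ACTIVE,
                        PotencySet(ac50=1.0), CUT)
    assert {"low.nconc", "low.nrep"} <= flags
    flags = apply_flags(_series([0, 0, 0, 30], n_rep=2), _fit(), ACTIVE,
                        PotencySet(ac50=1.0), CUT)
    assert "low.nconc" not in flags and "low.nrep" not in flags


def test_border_band_inclusive():
    for top, expect in [(10.0, True), (8.0, True), (12.0, True),
                        (7.9, False), (12.1, False)]:
        flags = apply_flags(_series([0, 0, 0, top]), _fit(top=top), ACTIVE,
                            PotencySet(ac50=1.0), CUT)
        assert ("border" in flags) is expect


def test_single_point_flags_mutually_exclusive():
    high = apply_flags(_series([0, 0, 0, 30]), _fit(), ACTIVE,
                       PotencySet(ac50=1.0), CUT)
    assert "singlept.hit.high" in high and "singlept.hit.mid" not in high
    mid = apply_flags(_series([0, 0, 30, 0]), _fit(), ACTIVE,
                      PotencySet(ac50=1.0), CUT)
    assert "singlept.hit.mid" in mid and "singlept.hit.high" not in mid


def test_multipoint_inactive():
    flags = apply_flags(_series([0, 0, 20, 20]), _fit(), INACTIVE, PotencySet(), CUT)
    assert "multipoint.neg" in flags
    flags = apply_flags(_series([0, 0, 0, 20]), _fit(), INACTIVE, PotencySet(), CUT)
    assert "multipoint.neg" not in flags


def test_noise_flag_compares_rmse_to_cutoff():
    flags = apply_flags(_series([0, 0, 0, 30]), _fit(rmse=11.0), ACTIVE,
                        PotencySet(ac50=1.0), CUT)
    assert "noise" in flags


def test_gnls_lowconc_and_viability():
    gnls_params = {"tp": 30.0, "ga": 0.01, "p": 2.0, "la": 1.0, "q": 2.0, "er": 0.0}
    s = _series([0, 10, 30, 10])
    flags = apply_flags(s, _fit(model_id="gnls", params=gnls_params), ACTIVE,
                        PotencySet(ac50=0.5), CUT,
                        EndpointMeta(cell_viability=True))
    assert "gnls.lowconc" in flags  # ga below lowest tested conc
    assert "viability.gnls" in flags
    # hill winner on a viability endpoint: no gnls flags
    flags = apply_flags(s, _fit(), ACTIVE, PotencySet(ac50=0.5), CUT,
                        EndpointMeta(cell_viability=True))
    assert "viability.gnls" not in flags and "gnls.lowconc" not in flags


def test_ac50_below_range_flagged():
    flags = apply_flags(_series([0, 0, 0, 30]), _fit(), ACTIVE,
                        PotencySet(ac50=0.01), CUT)
    assert "ac50.lowconc" in flags


def test_directionality_failure():
    flags = apply_flags(_series([-8, 0, 0, 8]), _fit(), INACTIVE, PotencySet(), CUT)
    assert "modl.directionality.fail" in flags
    flags = apply_flags(_series([0, 0, 4, 8]), _fit(), INACTIVE, PotencySet(), CUT)
    assert "modl.directionality.fail" not in flags


def test_efficacy_threshold_follows_scale():
    s = _series([0, 0, 0, 30])
    flags = apply_flags(s, _fit(top=30.0), ACTIVE, PotencySet(ac50=1.0), CUT,
                        EndpointMeta(scale="percent"))
    assert "efficacy.50" in flags  # 30 < 50 percent
    flags = apply_flags(s, _fit(top=30.0), ACTIVE, PotencySet(ac50=1.0), CUT,
                        EndpointMeta(scale="log2"))
    assert "efficacy.50" not in flags  # 30 >> log2(1.5)


def test_flags_are_pure_and_documented():
    args = (_series([0, 0, 20, 30]), _fit(), ACTIVE, PotencySet(ac50=1.0, bmd=5.0), CUT)
    first, second = apply_flags(*args), apply_flags(*args)
    assert first == second
    assert first <= set(FLAG_DESCRIPTIONS)
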