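"""Continuous hit call: three-weight product, limits, binarization."""

import numpy as np
import pytest

from concresp.baseline import CutoffSpec
from concresp.fitting import WinnerResult, fit_all
from concresp.hitcall import binarize, continuous_hitcall
from concresp.hitcall import _w_median
from concresp.models import evaluate
from concresp.synth import SimConfig, simulate_series
from tests.conftest import make_series

CUT10 = CutoffSpec(bmad=10 / 3, onesd=10 / 1.349, coff=10.0)


def _grid(n_rep=3):
    return np.repeat(0.03 * 10 ** (0.5 * np.arange(8)), n_rep)


def test_three_concentration_series_scores_zero():
    s = make_series([0.1, 1.0, 10.0] * 3, [0, 20, 50] * 3)
    winner = fit_all(s)
    hit = continuous_hitcall(s, winner, CUT10)
    assert hit.hitc == 0.0
    assert not hit.active
    assert winner.winning_model is None  # reported downstream as model "none"


def test_flat_zero_data_is_inactive():
    conc = _grid()
    s = make_series(conc, np.zeros(conc.size))
    hit = continuous_hitcall(s, fit_all(s), CUT10)
    assert hit.hitc < 0.05


def test_strong_clean_curve_is_confident_hit():
    conc = _grid()
    resp = evaluate("hill", {"tp": 100.0, "ga": 1.0, "p": 2.0}, conc)  # tp = 10*coff
    s = make_series(conc, resp)
    hit = continuous_hitcall(s, fit_all(s), CUT10)
    assert hit.hitc > 0.99
    assert hit.w_aic > 0.99 and hit.w_median > 0.99 and hit.w_top > 0.99


def test_constant_model_advantage_drives_hitc_to_zero():
    """A constant-model AIC 10 below the winner caps hitc below 0.01."""
    conc = _grid()
    rng = np.random.default_rng(2)
    s = make_series(conc, evaluate("hill", {"tp": 100, "ga": 1, "p": 2}, conc)
                    + rng.normal(0, 2, conc.size))
    winner = fit_all(s)
    handicapped = WinnerResult(winner.winning_model, winner.fits,
                               aic_constant=winner.winner.aic - 10.0)
    hit = continuous_hitcall(s, handicapped, CUT10)
    assert hit.hitc < 0.01


def test_product_decomposition_and_range():
    rng = np.random.default_rng(9)
    conc = _grid()
    for tp in (0.0, 8.0, 30.0):
        resp = evaluate("exp4", {"tp": tp, "ga": 1.0}, conc) if tp else np.zeros(conc.size)
        s = make_series(conc, resp + rng.normal(0, 3, conc.size))
        hit = continuous_hitcall(s, fit_all(s), CUT10)
        assert 0.0 <= hit.hitc <= 1.0
        for w in (hit.w_aic, hit.w_median, hit.w_top):
            assert 0.0 <= w <= 1.0
        assert hit.hitc == pytest.approx(hit.w_aic * hit.w_median * hit.w_top, abs=1e-12)


def test_hitc_monotone_in_efficacy():
    """Scaling up a hill top never lowers the hit call (fixed noise draw)."""
    conc = _grid()
    noise = np.random.default_rng(31).normal(0, 2.0, conc.size)
    hitcs = []
    for tp in (2.0, 10.0, 20.0, 40.0, 80.0):
        resp = evaluate("hill", {"tp": tp, "ga": 1.0, "p": 2.0}, conc) + noise
        s = make_series(conc, resp)
        hitcs.append(continuous_hitcall(s, fit_all(s), CUT10).hitc)
    assert all(b >= a - 1e-6 for a, b in zip(hitcs, hitcs[1:]))
    assert hitcs[0] < 0.5 < hitcs[-1]


def test_median_dialects_agree_without_replicates():
    conc = _grid(n_rep=1)
    rng = np.random.default_rng(12)
    s = make_series(conc, evaluate("hill", {"tp": 25, "ga": 1, "p": 2}, conc)
                    + rng.normal(0, 3, conc.size))
    winner = fit_all(s)
    h_med = continuous_hitcall(s, winner, CUT10, dialect="v4.1_median")
    h_rep = continuous_hitcall(s, winner, CUT10, dialect="v4.0_replicate")
    assert h_med.hitc == h_rep.hitc


def test_w_median_matches_monte_carlo_tail():
    """The median-exceedance weight equals its t(4)-tail definition."""
    conc = _grid()
    rng = np.random.default_rng(6)
    s = make_series(conc, evaluate("exp4", {"tp": 14.0, "ga": 1.0}, conc)
                    + rng.normal(0, 3, conc.size))
    fit = fit_all(s).winner
    w = _w_median(s, fit, CUT10.coff, "v4.1_median")
    # Monte-Carlo oracle of the defining model: per-concentration medians are
    # t(4) around the fitted curve with scale exp(er)/sqrt(n)
    uniq, _, cnt = s.groups()
    mu = evaluate(fit.model_id, fit.params, uniq)
    scale = np.exp(fit.params["er"]) / np.sqrt(cnt)
    draws = np.random.default_rng(99).standard_t(4, size=(200_000, uniq.size))
    p_mc = np.abs(mu + draws * scale) >= CUT10.coff
    assert w == pytest.approx(float(p_mc.mean(axis=0).max()), abs=0.01)


def test_binarize_threshold_semantics():
    assert binarize(0.90) is True
    assert binarize(0.8999) is False
    assert binarize(0.0) is False
    assert binarize(0.5, threshold=0.5) is True
    with pytest.raises(ValueError):
        binarize(1.2)
    with pytest.raises(ValueError):
        binarize(-0.1)
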