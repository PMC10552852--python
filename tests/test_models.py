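"""Model equations, modeled top, and concentration inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concresp.models import (
    GNLS_MIN_WIDTH,
    MODEL_IDS,
    MODELS,
    evaluate,
    inverse_conc,
    model_top,
)

GNLS_PARAMS = {"tp": 50.0, "ga": 0.1, "p": 4.0, "la": 30.0, "q": 4.0}


@pytest.mark.parametrize(
    "model_id, params, conc, expected",
    [
        ("constant", {}, 10.0, 0.0),
        ("hill", {"tp": 50, "ga": 1, "p": 2}, 1.0, 25.0),  # half-max at ga
        ("exp4", {"tp": 40, "ga": 1}, 1.0, 20.0),  # 1 - 2^-1 = 1/2
        ("poly1", {"a": 2}, 3.0, 6.0),
        ("poly2", {"a": 3, "b": 2}, 2.0, 6.0),  # u + u^2 = 2 at x = b
        ("power", {"a": 2, "p": 3}, 2.0, 16.0),
        ("exp2", {"a": 1, "b": 1}, 1.0, math.e - 1),
        ("exp5", {"tp": 40, "ga": 2, "p": 1}, 2.0, 20.0),
    ],
)
def test_evaluate_known_values(model_id, params, conc, expected):
    assert evaluate(model_id, params, conc) == pytest.approx(expected, rel=1e-12)


def test_param_counts_include_error_scale():
    expected = {"constant": 1, "poly1": 2, "poly2": 3, "power": 3, "exp2": 3,
                "exp4": 3, "exp3": 4, "exp5": 4, "hill": 4, "gnls": 6}
    assert {m: MODELS[m].n_params for m in MODEL_IDS} == expected


@pytest.mark.parametrize("model_id", [m for m in MODEL_IDS if m != "constant"])
def test_origin_limit(model_id):
    """Every curve vanishes as concentration approaches zero."""
    params = {"tp": 30.0, "ga": 1.0, "p": 1.5, "la": 1.0 * 10**GNLS_MIN_WIDTH,
              "q": 2.0, "a": 5.0, "b": 2.0}
    assert abs(evaluate(model_id, params, 1e-12)) < 1e-6


def test_evaluate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        evaluate("sigmoid", {}, 1.0)
    with pytest.raises(ValueError):
        evaluate("poly1", {"a": 1.0}, 0.0)
    with pytest.raises(ValueError):
        evaluate("hill", {"tp": 1.0, "ga": -1.0, "p": 1.0}, 1.0)
    with pytest.raises(ValueError):
        # gnls narrower than the minimum width
        evaluate("gnls", {"tp": 1, "ga": 1, "p": 1, "la": 3, "q": 1}, 1.0)


def test_model_top_monotone_at_cmax():
    top, top_conc = model_top("poly1", {"a": 2.0}, (0.1, 10.0))
    assert (top, top_conc) == (20.0, 10.0)
    top, top_conc = model_top("hill", {"tp": -30.0, "ga": 1.0, "p": 1.0}, (0.001, 100.0))
    assert top_conc == 100.0
    assert top == pytest.approx(evaluate("hill", {"tp": -30, "ga": 1, "p": 1}, 100.0))
    assert top == pytest.approx(-29.7, abs=0.05)


def test_gnls_interior_top_matches_brute_force():
    rng = (0.001, 100.0)
    top, top_conc = model_top("gnls", GNLS_PARAMS, rng)
    assert rng[0] < top_conc < rng[1]
    grid = np.logspace(-3, 2, 20001)
    brute = evaluate("gnls", GNLS_PARAMS, grid)
    k = np.argmax(np.abs(brute))
    assert abs(top) >= abs(brute[k]) - 1e-9
    assert top_conc == pytest.approx(grid[k], rel=1e-3)


@pytest.mark.parametrize(
    "model_id, params, target, expected",
    [
        ("hill", {"tp": 50, "ga": 1, "p": 2}, 25.0, 1.0),
        ("exp5", {"tp": 50, "ga": 3, "p": 1.2}, 25.0, 3.0),
        ("poly1", {"a": 1}, 7.0, 7.0),
    ],
)
def test_inverse_known_values(model_id, params, target, expected):
    got = inverse_conc(model_id, params, target, (0.01, 100.0))
    assert got == pytest.approx(expected, rel=1e-9)


def test_inverse_unattained_is_absent():
    # target beyond the asymptote: absent, not an exception
    assert inverse_conc("hill", {"tp": 50, "ga": 1, "p": 2}, 60.0, (0.01, 100.0)) is None
    # wrong sign relative to the curve
    assert inverse_conc("poly1", {"a": 1.0}, -5.0, (0.01, 100.0)) is None


@pytest.mark.parametrize("model_id", ["hill", "exp4", "exp5"])
def test_half_max_inverse_equals_ga(model_id):
    params = {"tp": 44.0, "ga": 0.7, "p": 1.7}
    got = inverse_conc(model_id, params, 22.0, (1e-4, 1e4))
    assert got == pytest.approx(0.7, abs=1e-9)


def _random_params(model_id, rng):
    return {
        "tp": rng.uniform(5, 80) * rng.choice([-1, 1]),
        "a": rng.uniform(0.1, 5) * rng.choice([-1, 1]),
        "ga": 10 ** rng.uniform(-1.5, 1.5),
        "b": 10 ** rng.uniform(-0.5, 1.5),
        "p": rng.uniform(0.4, 4),
        "q": rng.uniform(0.4, 4),
    }


def test_inverse_evaluate_round_trip():
    """inverse(f(x)) == x to 1e-6 relative, over seeded random draws."""
    rng = np.random.default_rng(20240901)
    window = (1e-3, 1e3)
    n = 0
    while n < 1000:
        model_id = str(rng.choice([m for m in MODEL_IDS if m not in ("constant", "gnls")]))
        params = _random_params(model_id, rng)
        x = 10 ** rng.uniform(-2.5, 2.5)
        y = evaluate(model_id, params, x)
        if abs(y) < 1e-12 or not math.isfinite(y):
            continue
        if "tp" in MODELS[model_id].param_names and abs(y) > 0.999 * abs(params["tp"]):
            continue  # saturated plateau: inversion is ill-conditioned there
        back = inverse_conc(model_id, params, y, window)
        assert back is not None
        assert back == pytest.approx(x, rel=1e-6)
        n += 1


def test_inverse_round_trip_gnls_rising_limb():
    rng = np.random.default_rng(5)
    for _ in range(100):
        params = {"tp": rng.uniform(5, 80), "ga": 10 ** rng.uniform(-1, 0),
                  "p": rng.uniform(0.5, 4), "q": rng.uniform(0.5, 4)}
        params["la"] = params["ga"] * 10 ** rng.uniform(GNLS_MIN_WIDTH, GNLS_MIN_WIDTH + 1)
        _, peak_conc = model_top("gnls", params, (1e-4, 1e4))
        x = 10 ** np.random.default_rng(1).uniform(math.log10(1e-3), math.log10(peak_conc))
        y = evaluate("gnls", params, x)
        back = inverse_conc("gnls", params, y, (1e-4, 1e4))
        assert back == pytest.approx(x, rel=1e-5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    model_id=st.sampled_from(["hill", "exp4", "exp5"]),
    tp=st.floats(1.0, 100.0).map(lambda v: round(v, 6)),
    ga=st.floats(0.01, 100.0).map(lambda v: round(v, 6)),
    p=st.floats(0.35, 6.0).map(lambda v: round(v, 6)),
    sign=st.sampled_from([1.0, -1.0]),
)
def test_half_max_crossing_is_ga_property(model_id, tp, ga, p, sign):
    """For the sigmoidal families the half-max crossing is ga exactly,
    in either response direction."""
    params = {"tp": sign * tp, "ga": ga, "p": p}
    got = inverse_conc(model_id, params, sign * tp / 2.0, (ga * 1e-4, ga * 1e4))
    assert got == pytest.approx(ga, rel=1e-7)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    a=st.floats(-5.0, 5.0).filter(lambda v: abs(v) > 1e-3),
    x1=st.floats(0.01, 99.0),
    x2=st.floats(0.01, 99.0),
)
def test_poly1_superposition_property(a, x1, x2):
    y1 = evaluate("poly1", {"a": a}, x1)
    y2 = evaluate("poly1", {"a": a}, x2)
    assert evaluate("poly1", {"a": a}, x1 + x2) == pytest.approx(y1 + y2, rel=1e-12)


@pytest.mark.parametrize("model_id", [m for m in MODEL_IDS if MODELS[m].monotone])
def test_monotone_models_are_monotone_in_conc(model_id):
    params = {"tp": 30.0, "ga": 1.0, "p": 1.5, "a": 5.0, "b": 20.0, "q": 2.0}
    grid = np.logspace(-3, 2, 200)
    vals = evaluate(model_id, params, grid) if model_id != "constant" else np.zeros(200)
    assert np.all(np.diff(vals) >= -1e-9)
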