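"""Logistic fitting, coefficient comparison and weight-rule derivation."""

import math

import numpy as np
import pandas as pd
import pytest

from apmscore.derive import (
    CoefficientComparison,
    LogisticFit,
    RiskCurve,
    SeparationError,
    compare_coefficients,
    derive_category_weights,
    derive_linear_rule,
    estimate_risk_curve,
    fit_logistic,
    select_breakpoints,
)
from apmscore.severity import ValidationError

from conftest import logistic_cohort


def cohort_from_2x2(exposed_dead, exposed_alive, ref_dead, ref_alive):
    x = [1] * (exposed_dead + exposed_alive) + [0] * (ref_dead + ref_alive)
    y = [1] * exposed_dead + [0] * exposed_alive + \
        [1] * ref_dead + [0] * ref_alive
    return np.array(y), pd.DataFrame({"exposed": x})


def fake_fit(**coefs) -> LogisticFit:
    """A LogisticFit with prescribed coefficients (SEs irrelevant to the test)."""
    params = pd.Series({"intercept": 0.0, **coefs})
    ones = pd.Series(1.0, index=params.index)
    return LogisticFit(params=params, bse=ones, pvalues=ones, llf=0.0,
                       converged=True, nobs=100)


# ---------------------------------------------------------------------------
# fit_logistic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table", [
    (23, 5, 10, 121),    # thin-vs-reference counts from a 3-group mortality table
    (40, 60, 25, 75),
    (8, 2, 3, 12),
])
def test_2x2_fit_matches_cross_product_ratio(table):
    a, b, c, d = table
    y, X = cohort_from_2x2(a, b, c, d)
    fit = fit_logistic(y, X)
    assert math.exp(fit.params["exposed"]) == pytest.approx(
        (a * d) / (b * c), rel=1e-6)


def test_crude_or_on_printed_group_counts():
    """HIGH 23 dead/5 alive vs REF 10 dead/121 alive -> crude OR 55.66."""
    y, X = cohort_from_2x2(23, 5, 10, 121)
    fit = fit_logistic(y, X)
    assert math.exp(fit.params["exposed"]) == pytest.approx(55.66, abs=0.005)


def test_null_association_gives_or_one():
    y, X = cohort_from_2x2(30, 30, 30, 30)
    fit = fit_logistic(y, X)
    assert math.exp(fit.params["exposed"]) == pytest.approx(1.0, abs=1e-8)


def test_or_equals_exp_b_and_ci_ordered():
    y, X = cohort_from_2x2(20, 40, 10, 50)
    fit = fit_logistic(y, X)
    ci = fit.conf_int()
    assert fit.odds_ratios["exposed"] == pytest.approx(
        math.exp(fit.params["exposed"]))
    assert ci.loc["exposed", "low"] < ci.loc["exposed", "or"] < ci.loc["exposed", "high"]


def test_separation_raises_named_error():
    rng = np.random.default_rng(0)
    x = rng.normal(size=80)
    y = (x > 0).astype(int)   # complete separation on 'marker'
    with pytest.raises(SeparationError, match="marker|separation"):
        fit_logistic(y, pd.DataFrame({"marker": x}))


def test_single_class_and_constant_predictor_rejected():
    with pytest.raises(ValidationError, match="both classes"):
        fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10)}))
    y = np.array([0, 1] * 5)
    with pytest.raises(ValidationError, match="constant"):
        fit_logistic(y, pd.DataFrame({"x": np.ones(10)}))


# ---------------------------------------------------------------------------
# coefficient comparison and the linear rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("b_a, b_b, close", [
    (0.4, 0.4, True),            # identity
    (0.5, 0.3, False),           # |0.2| > 0.25 * 0.5
    (-0.45, 0.40, True),         # sign-aligned |0.05| <= 0.1125
])
def test_compare_coefficients(b_a, b_b, close):
    fit = fake_fit(apm=b_a, gcs_pts=b_b)
    assert compare_coefficients(fit, "apm", "gcs_pts").close is close


def test_compare_missing_predictor_errors():
    with pytest.raises(ValidationError, match="not present"):
        compare_coefficients(fake_fit(apm=0.3), "apm", "gcs_pts")


def test_derive_linear_rule_gated_on_closeness():
    close = compare_coefficients(fake_fit(apm=-0.4, gcs_pts=0.42), "apm", "gcs_pts")
    rule, info = derive_linear_rule(close, anchor=15)
    assert rule is not None and rule.kind == "linear_anchor"
    assert rule.points(12) == 3
    rule14, _ = derive_linear_rule(close, anchor=14)
    assert rule14.points(12) == 2

    far = compare_coefficients(fake_fit(apm=-0.9, gcs_pts=0.3), "apm", "gcs_pts")
    rule, info = derive_linear_rule(far)
    assert rule is None
    assert info["ratio"] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# risk curve and breakpoints
# ---------------------------------------------------------------------------

def test_risk_curve_recovers_known_logistic():
    a, b = 4.73, -0.473
    df = logistic_cohort(10_000, a, b, seed=1)
    curve = estimate_risk_curve(df)
    truth = 1 / (1 + np.exp(-(a + b * curve.grid)))
    assert curve.method == "logistic"
    assert np.max(np.abs(curve.prob - truth)) < 0.03


def test_risk_curve_flat_cohort_recovers_prevalence():
    df = logistic_cohort(10_000, math.log(0.3 / 0.7), 0.0, seed=2)
    curve = estimate_risk_curve(df)
    assert np.max(np.abs(curve.prob - 0.3)) < 0.03


def test_risk_curve_separation_falls_back_to_empirical():
    t = np.array([6.0] * 30 + [20.0] * 30)
    y = np.array([1] * 30 + [0] * 30)
    df = pd.DataFrame({"apm_mm": t, "death": y})
    with pytest.warns(UserWarning, match="empirical"):
        curve = estimate_risk_curve(df)
    assert curve.method == "empirical"
    assert curve.prob[0] >= curve.prob[-1]


def test_risk_curve_preconditions():
    small = logistic_cohort(10, 0.0, 0.0, seed=3)
    with pytest.raises(ValidationError, match="20 patients"):
        estimate_risk_curve(small)
    one_class = pd.DataFrame({"apm_mm": np.arange(6, 31, dtype=float),
                              "death": np.zeros(25, dtype=int)})
    with pytest.raises(ValidationError, match="both outcomes"):
        estimate_risk_curve(one_class)


def test_breakpoints_at_steepest_slope_below_median():
    # 0.5-crossing at t=10 -> lower cutpoint lands on the 10 mm grid point
    df = logistic_cohort(20_000, 4.73, -0.473, seed=4)
    curve = estimate_risk_curve(df)
    (lo, hi), prov = select_breakpoints(curve, cohort_median=15)
    assert (lo, hi) == (10.0, 15.0)
    assert prov == "fitted"


def test_breakpoints_override_and_degenerate():
    df = logistic_cohort(20_000, 4.73, -0.473, seed=5)
    curve = estimate_risk_curve(df)
    (lo, hi), prov = select_breakpoints(curve, 15, override=(9, 14))
    assert (lo, hi) == (9.0, 14.0) and prov == "manual"
    flat = RiskCurve(grid=np.arange(6.0, 22.0), prob=np.full(16, 0.3),
                     method="logistic", empirical=pd.DataFrame(),
                     intercept=math.log(0.3 / 0.7), slope=0.0)
    with pytest.raises(ValidationError, match="degenerate"):
        select_breakpoints(flat, 15)


# ---------------------------------------------------------------------------
# categorical weights
# ---------------------------------------------------------------------------

def test_category_weights_from_printed_ors():
    fit = fake_fit(apm_high=math.log(40.7), apm_mid=math.log(6.9))
    rule = derive_category_weights(fit)
    assert rule.weights == (41, 7, 0)   # half-away rounding of 40.7 and 6.9
    rule_tr = derive_category_weights(fit, rounding="truncate")
    assert rule_tr.weights == (40, 6, 0)


def test_category_weight_rounding_half_away():
    fit = fake_fit(apm_high=math.log(2.49), apm_mid=math.log(1.5))
    assert derive_category_weights(fit).weights == (2, 2, 0)


def test_category_weights_must_be_monotone():
    fit = fake_fit(apm_high=math.log(3.0), apm_mid=math.log(5.0))
    with pytest.raises(ValidationError, match="monotone|increase"):
        derive_category_weights(fit)


def test_protective_category_rejected():
    fit = fake_fit(apm_high=math.log(4.0), apm_mid=math.log(0.8))
    with pytest.raises(ValidationError, match="protective"):
        derive_category_weights(fit)


def test_category_weights_invariant_to_column_order():
    rng = np.random.default_rng(6)
    cat = rng.choice([0, 1, 2], size=4000, p=[0.15, 0.45, 0.4])
    p = np.array([0.75, 0.4, 0.1])[cat]
    y = (rng.uniform(size=4000) < p).astype(int)
    ind = pd.DataFrame({"apm_high": (cat == 0).astype(float),
                        "apm_mid": (cat == 1).astype(float)})
    w1 = derive_category_weights(fit_logistic(y, ind[["apm_high", "apm_mid"]]))
    w2 = derive_category_weights(fit_logistic(y, ind[["apm_mid", "apm_high"]]))
    assert w1.weights == w2.weights
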