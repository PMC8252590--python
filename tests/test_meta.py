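"""Random-effects pooling, Hartung-Knapp intervals, prediction intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logit

from siecv import (EstimationError, pool, pool_transformed,
                   prediction_interval)


def test_dersimonian_laird_hand_example():
    # values (1, 3), SEs (1, 1): Q = 2, df = 1, C = 1 -> tau2 = 1, pooled 2
    p = pool([1.0, 3.0], [1.0, 1.0], method="DL")
    assert p.value == pytest.approx(2.0)
    assert p.tau2 == pytest.approx(1.0)


def test_zero_dispersion_collapses():
    p = pool([0.5] * 5, [0.3, 0.1, 0.9, 0.2, 0.4], method="REML")
    assert p.value == pytest.approx(0.5)
    assert p.tau2 == 0.0 and p.var_hk == 0.0


def test_equal_weights_give_arithmetic_mean():
    vals = [0.2, 0.4, 0.9]
    p = pool(vals, [0.5] * 3, method="FE")
    assert p.value == pytest.approx(np.mean(vals))


@pytest.mark.parametrize("method", ["DL", "PM", "REML"])
def test_estimators_agree_on_homogeneous_inputs(method):
    p = pool([1.2] * 6, [0.2, 0.3, 0.4, 0.5, 0.6, 0.7], method=method)
    assert p.tau2 == pytest.approx(0.0, abs=1e-8)
    assert p.value == pytest.approx(1.2)


def test_pooled_value_is_convex_combination(rng):
    for _ in range(50):
        vals = rng.normal(size=8)
        ses = rng.uniform(0.1, 1.0, size=8)
        for method in ("DL", "PM", "REML", "FE"):
            p = pool(vals, ses, method=method)
            assert vals.min() - 1e-12 <= p.value <= vals.max() + 1e-12
            assert p.tau2 >= 0 and np.all(p.weights > 0)


def test_dl_matches_statsmodels(rng):
    statsmodels = pytest.importorskip("statsmodels.stats.meta_analysis")
    vals = rng.normal(0.5, 0.4, size=9)
    ses = rng.uniform(0.1, 0.6, size=9)
    ours = pool(vals, ses, method="DL")
    ref = statsmodels.combine_effects(vals, ses ** 2, method_re="chi2")
    assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-8)
    assert ours.value == pytest.approx(ref.mean_effect_re, rel=1e-8)


def test_paule_mandel_solves_generalized_q(rng):
    vals = rng.normal(0, 1, size=10)
    ses = rng.uniform(0.2, 0.8, size=10)
    p = pool(vals, ses, method="PM")
    w = 1 / (ses ** 2 + p.tau2)
    mu = w @ vals / w.sum()
    assert w @ (vals - mu) ** 2 == pytest.approx(len(vals) - 1, abs=1e-5)


def test_hartung_knapp_ci_uses_t_quantile():
    vals = [0.2, 0.5, 0.9, 1.4]
    ses = [0.2, 0.3, 0.25, 0.4]
    p = pool(vals, ses, method="DL")
    half = stats.t.ppf(0.975, 3) * p.se_hk
    assert p.ci_upper - p.value == pytest.approx(half)
    assert p.value - p.ci_lower == pytest.approx(half)


def test_prediction_interval_t_quantile_example():
    from siecv.meta import PooledEstimate
    p = PooledEstimate(value=0.0, tau2=1.0, var_conventional=0.0,
                       var_hk=0.0, weights=np.ones(12), q=12, method="DL")
    pi = prediction_interval(p, level=0.95)
    t10 = stats.t.ppf(0.975, 10)
    assert pi.upper == pytest.approx(t10, abs=1e-6)  # 2.228...
    assert pi.lower == pytest.approx(-t10, abs=1e-6)


def test_prediction_interval_contains_ci(rng):
    for _ in range(30):
        vals = rng.normal(size=6)
        ses = rng.uniform(0.1, 0.5, size=6)
        p = pool(vals, ses, method="DL")
        pi = prediction_interval(p)
        assert pi.lower <= p.ci_lower + 1e-12
        assert pi.upper >= p.ci_upper - 1e-12


def test_prediction_interval_flagged_below_three():
    p = pool([1.0, 2.0], [0.5, 0.5], method="DL")
    pi = prediction_interval(p)
    assert not pi.defined and np.isnan(pi.lower)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(c=st.floats(0.1, 10.0))
def test_pool_is_scale_equivariant(c):
    vals = np.array([0.3, -0.2, 0.9, 0.5])
    ses = np.array([0.2, 0.4, 0.3, 0.25])
    base = pool(vals, ses, method="DL")
    scaled = pool(c * vals, c * ses, method="DL")
    assert scaled.value == pytest.approx(c * base.value, rel=1e-9)
    assert scaled.tau == pytest.approx(c * base.tau, rel=1e-9, abs=1e-12)
    assert scaled.ci_lower == pytest.approx(c * base.ci_lower, rel=1e-9)
    pi_b = prediction_interval(base)
    pi_s = prediction_interval(scaled)
    assert pi_s.upper == pytest.approx(c * pi_b.upper, rel=1e-9)


def test_logit_pooling_backtransforms():
    # identity: delegates to pool
    p_id = pool_transformed([0.6, 0.8], [0.05, 0.05], transform="identity",
                            method="FE")
    assert p_id.value == pytest.approx(0.7)
    # all 0.5 is the fixed point of the logit at 0
    p_half = pool_transformed([0.5] * 4, [0.02] * 4, transform="logit",
                              method="REML")
    assert p_half.value == pytest.approx(0.5)
    # FE, equal raw SEs: weights differ after the delta method; oracle below
    vals = np.array([0.6, 0.8])
    ses = np.array([0.05, 0.05])
    tses = ses / (vals * (1 - vals))
    w = 1 / tses ** 2
    expected = expit(w @ logit(vals) / w.sum())
    p = pool_transformed(vals, ses, transform="logit", method="FE")
    assert p.value == pytest.approx(expected, abs=1e-10)
    # the delta method upweights the estimate nearer 0.5, so the pooled
    # value sits below the naive equal-weight back-transform
    assert p.value < expit(np.mean(logit(vals)))


def test_pool_input_contracts():
    with pytest.raises(EstimationError):
        pool([1.0], [0.5])
    with pytest.raises(EstimationError):
        pool([1.0, 2.0], [0.5, -0.1])
    with pytest.raises(Exception):
        pool_transformed([0.5, 1.2], [0.1, 0.1], transform="logit")


def test_tau2_estimator_recovery_small():
    """Each estimator's mean tau2-hat is near the generating value."""
    rng = np.random.default_rng(11)
    true_tau2 = 0.2
    ses = rng.uniform(0.2, 0.5, size=30)
    means = {"DL": [], "PM": [], "REML": []}
    for _ in range(200):
        theta = rng.normal(0.0, np.sqrt(true_tau2), size=30)
        y = theta + rng.normal(0.0, ses)
        for m in means:
            means[m].append(pool(y, ses, method=m).tau2)
    for m, vals in means.items():
        assert np.mean(vals) == pytest.approx(true_tau2, abs=0.05), m
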