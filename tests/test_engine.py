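"""IECV loop, stepwise selection control flow, and the global model."""

import numpy as np
import pytest
from scipy.special import expit

import siecv.engine as engine
from siecv import (EstimationError, GeneratorConfig, ModelSpec,
                   PredictorSpec, fit_global, generate, iecv,
                   interaction_guard, main_term, siecv, siecv_backward)
from siecv.data import INTERCEPT, interaction_term
from siecv.losses import AggregatedLoss
from siecv.reporting import dumps, trace_to_dict


def _tiny(K=3, n=80, seed=5, **kw):
    cfg = GeneratorConfig(
        K=K, cluster_sizes=n, mu_alpha=-0.8, sigma_alpha=0.2,
        predictors=(PredictorSpec("x", mu_beta=1.0, tau=0.1),), seed=seed,
        **kw,
    )
    return generate(cfg)[0]


def test_iecv_structure_k3():
    data = _tiny(K=3)
    result = iecv(data, ModelSpec([main_term("x")]), tau_estimator="DL")
    assert len(result.holdouts) == 3
    # with K=3 each development pool has exactly 2 cluster fits
    for h in result.holdouts:
        assert set(h.coefficients) == {INTERCEPT, "x"}
    assert {h.cluster for h in result.holdouts} == set(data.cluster_labels)
    assert set(result.pooled) <= {"mse", "cal_slope", "cal_in_large",
                                  "c_statistic"}


def test_iecv_intercept_only_predicts_constant():
    data = _tiny(K=4)
    result = iecv(data, ModelSpec([]), metrics=("mse",), tau_estimator="DL")
    for h in result.holdouts:
        rate = expit(h.coefficients[INTERCEPT])
        # MSE of a constant prediction p against y: mean((y - p)^2)
        y = data.outcome(h.cluster)
        assert h.performance["mse"].value == pytest.approx(
            np.mean((y - rate) ** 2))


def test_iecv_homogeneous_data_calibrates(rng):
    cfg = GeneratorConfig(
        K=8, cluster_sizes=800, mu_alpha=-1.0, sigma_alpha=0.0,
        predictors=(PredictorSpec("x", mu_beta=1.0, tau=0.0,
                                  kind="continuous"),), seed=17,
    )
    data, _ = generate(cfg)
    result = iecv(data, ModelSpec([main_term("x")]), tau_estimator="REML")
    slope = result.pooled["cal_slope"]
    assert slope.ci_lower <= 1.0 <= slope.ci_upper
    assert slope.tau < 0.25


def test_iecv_leakage_outcomes_of_holdout_do_not_touch_coefficients():
    data = _tiny(K=4, n=100)
    spec = ModelSpec([main_term("x")])
    result = iecv(data, spec, metrics=("mse",), tau_estimator="DL")
    h = data.cluster_labels[0]
    flipped = data.frame.copy()
    rows = flipped[data.cluster_col] == h
    flipped.loc[rows, data.outcome_col] = \
        1 - flipped.loc[rows, data.outcome_col]
    from siecv import ClusteredDataset
    perturbed = ClusteredDataset(flipped, data.cluster_col, data.outcome_col)
    result2 = iecv(perturbed, spec, metrics=("mse",), tau_estimator="DL")
    c1 = next(x for x in result.holdouts if x.cluster == h).coefficients
    c2 = next(x for x in result2.holdouts if x.cluster == h).coefficients
    for term in c1:
        assert c1[term] == c2[term]


def test_iecv_requires_three_viable_clusters():
    data = _tiny(K=3)
    frame = data.frame.copy()
    # make one cluster all non-events: validation-only
    label = data.cluster_labels[0]
    frame.loc[frame[data.cluster_col] == label, data.outcome_col] = 0
    from siecv import ClusteredDataset
    broken = ClusteredDataset(frame, data.cluster_col, data.outcome_col)
    with pytest.raises(EstimationError):
        iecv(broken, ModelSpec([main_term("x")]))


def test_forward_selection_prefers_signal(small_clustered,
                                          two_candidate_spec):
    data, _ = small_clustered
    trace = siecv(data, two_candidate_spec, loss="re", lam=0.5,
                  tau_estimator="DL")
    assert trace.cycles[1].selected == "signal"
    assert "signal" in [t.name for t in trace.final_spec.included]
    assert trace.stopping_reason in ("no_improvement",
                                     "candidates_exhausted")


def test_greedy_argmin_matches_brute_force(small_clustered,
                                           two_candidate_spec):
    """Independently recomputing every candidate loss reproduces each
    cycle's selection exactly."""
    data, _ = small_clustered
    trace = siecv(data, two_candidate_spec, loss="re", lam=0.5,
                  tau_estimator="DL")
    from siecv.losses import aggregate
    current = two_candidate_spec
    for cycle in trace.cycles[1:]:
        if not cycle.candidate_losses:
            break
        recomputed = {}
        for cand in current.candidates:
            res = iecv(data, current.with_candidate(cand), metrics=("mse",),
                       tau_estimator="DL")
            recomputed[cand.name] = aggregate(
                res.metric_values("mse"), "re", lam=0.5, method="DL").value
        for name, value in cycle.candidate_losses.items():
            assert value == pytest.approx(recomputed[name], abs=1e-12)
        best = min(recomputed, key=recomputed.get)
        if cycle.selected is not None:
            assert cycle.selected == best
            current = current.with_candidate(
                next(t for t in current.candidates if t.name == best))


def test_trace_bit_identical_across_runs(small_clustered,
                                         two_candidate_spec):
    data, _ = small_clustered
    t1 = siecv(data, two_candidate_spec, loss="re", lam=0.5,
               tau_estimator="DL")
    t2 = siecv(data, two_candidate_spec, loss="re", lam=0.5,
               tau_estimator="DL")
    assert dumps(trace_to_dict(t1)) == dumps(trace_to_dict(t2))


def _stub_engine(monkeypatch, values):
    """Drive the stepwise control flow with a prescribed loss per term set."""

    def fake_evaluate(data, spec, **kwargs):
        key = frozenset(t.name for t in spec.included)
        return AggregatedLoss("re", values[key], lam=0.5)

    def fake_iecv(data, spec, **kwargs):
        return engine.IECVResult(spec, [], {}, {})

    monkeypatch.setattr(engine, "_evaluate", fake_evaluate)
    monkeypatch.setattr(engine, "iecv", fake_iecv)


def test_stopping_no_improvement(monkeypatch):
    spec = ModelSpec([], set(), [main_term("a"), main_term("b")])
    _stub_engine(monkeypatch, {
        frozenset(): 0.10,
        frozenset({"a"}): 0.12,
        frozenset({"b"}): 0.15,
    })
    trace = siecv(None, spec)
    assert trace.stopping_reason == "no_improvement"
    assert trace.final_spec.term_names == [INTERCEPT]
    assert len(trace.cycles) == 2  # baseline + exactly one evaluated cycle
    assert trace.cycles[1].selected is None


def test_stopping_candidates_exhausted(monkeypatch):
    spec = ModelSpec([], set(), [main_term("a"), main_term("b")])
    _stub_engine(monkeypatch, {
        frozenset(): 0.30,
        frozenset({"a"}): 0.20,
        frozenset({"b"}): 0.25,
        frozenset({"a", "b"}): 0.10,
    })
    trace = siecv(None, spec)
    assert trace.stopping_reason == "candidates_exhausted"
    assert [c.selected for c in trace.cycles] == ["<baseline>", "a", "b"]
    assert trace.final_spec.term_names == [INTERCEPT, "a", "b"]


def test_tie_breaks_to_earlier_candidate(monkeypatch):
    spec = ModelSpec([], set(), [main_term("a"), main_term("b")])
    _stub_engine(monkeypatch, {
        frozenset(): 0.30,
        frozenset({"a"}): 0.20,
        frozenset({"b"}): 0.20,
        frozenset({"a", "b"}): 0.25,
    })
    trace = siecv(None, spec)
    assert trace.cycles[1].selected == "a"


def test_backward_respects_forced_terms(monkeypatch):
    spec = ModelSpec([main_term("keep"), main_term("drop1"),
                      main_term("drop2")], {"keep"}, [])
    _stub_engine(monkeypatch, {
        frozenset({"keep", "drop1", "drop2"}): 0.30,
        frozenset({"keep", "drop1"}): 0.28,
        frozenset({"keep", "drop2"}): 0.20,
        frozenset({"keep"}): 0.25,
    })
    trace = siecv_backward(None, spec)
    evaluated = set(trace.cycles[1].candidate_losses)
    assert "keep" not in evaluated
    assert trace.cycles[1].selected == "drop1"
    assert trace.final_spec.term_names == [INTERCEPT, "keep", "drop2"]
    assert trace.stopping_reason == "no_improvement"


def test_interaction_guard_rules():
    ab = interaction_term("a_x_b", ["a", "b"])
    only_a = ModelSpec([main_term("a")])
    both = ModelSpec([main_term("a"), main_term("b")])
    assert not interaction_guard(only_a, ab, require_main_effects=True)
    assert interaction_guard(both, ab, require_main_effects=True)
    assert interaction_guard(only_a, ab, require_main_effects=False)


def test_interaction_selection_locks_main_effects(monkeypatch):
    spec = ModelSpec([main_term("a"), main_term("b")], set(),
                     [interaction_term("a_x_b", ["a", "b"])])
    _stub_engine(monkeypatch, {
        frozenset({"a", "b"}): 0.30,
        frozenset({"a", "b", "a_x_b"}): 0.20,
    })
    trace = siecv(None, spec, require_main_effects=True)
    assert {"a", "b"} <= trace.final_spec.forced


def test_fit_global_shrinkage_arithmetic(small_clustered):
    data, _ = small_clustered
    spec = ModelSpec([main_term("signal")])
    unshrunk = fit_global(data, spec, None, tau_estimator="DL")
    assert unshrunk.shrinkage_slope == 1.0
    assert unshrunk.intercept_correction == 0.0
    assert unshrunk.shrunken == unshrunk.unshrunken

    result = iecv(data, spec, tau_estimator="DL")
    shrunk = fit_global(data, spec, result, tau_estimator="DL")
    s, a = shrunk.shrinkage_slope, shrunk.intercept_correction
    assert s == result.pooled["cal_slope"].value
    assert a == result.pooled["cal_in_large"].value
    assert shrunk.shrunken["signal"] == pytest.approx(
        s * shrunk.unshrunken["signal"])
    assert shrunk.shrunken[INTERCEPT] == pytest.approx(
        shrunk.unshrunken[INTERCEPT] + a)
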