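"""The IECV loop, stepwise predictor selection, and the final global model.

Internal-external cross-validation (IECV) splits clustered data by cluster:
each cluster is held out once, a model is developed on the remaining K - 1
clusters, and its performance is measured in the hold-out cluster.  Model
development is two-stage: every cluster is fitted once with Firth-penalized
logistic regression (stage 1), and for each hold-out cluster the other
clusters' coefficients are pooled term-wise by univariate random-effects
meta-analysis (stage 2).  Stage-1 fits depend only on the cluster's own
data, so they are computed once and cached; each hold-out evaluation merely
recombines them, which is what makes the stepwise search affordable.

Stepwise IECV (:func:`siecv`) grows a model greedily: each cycle evaluates
every remaining candidate term by a full IECV pass, collapses the K
hold-out MSEs with a configurable aggregated loss (see :mod:`.losses`), and
adds the term with the smallest loss.  The algorithm stops when the best
candidate no longer improves on the previous cycle, or when candidates run
out.  :func:`siecv_backward` mirrors this by removing terms from a full
model.  The procedure is entirely deterministic: ties break toward the
earlier position in the configured candidate ordering.

The final :func:`fit_global` model pools all K cluster fits (no hold-out)
and attaches shrinkage factors taken from the final cycle's IECV: slopes
are multiplied by the summary calibration slope and the summary
calibration-in-the-large is added to the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import (INTERCEPT, ClusteredDataset, ModelSpec, Term,
                   build_design, cluster_center_means)
from .errors import EstimationError
from .firth import ClusterFit, fit_firth, reestimate_intercept
from .losses import AggregatedLoss, aggregate
from .meta import (PooledEstimate, PredictionInterval, pool,
                   pool_transformed, prediction_interval)
from .performance import PerformanceEstimate, all_metrics, mse, predict

logger = logging.getLogger("siecv")

ALL_METRICS = ("mse", "cal_slope", "cal_in_large", "c_statistic")


@dataclass
class HoldoutEvaluation:
    cluster: object
    coefficients: dict              # development-pooled, term -> value
    performance: dict[str, PerformanceEstimate]


@dataclass
class IECVResult:
    spec: ModelSpec
    holdouts: list[HoldoutEvaluation]
    pooled: dict[str, PooledEstimate]
    intervals: dict[str, PredictionInterval]
    warnings: list[str] = field(default_factory=list)

    def metric_values(self, metric: str) -> list[PerformanceEstimate]:
        return [h.performance[metric] for h in self.holdouts
                if metric in h.performance and h.performance[metric].defined]


@dataclass
class CycleRecord:
    cycle: int
    candidate_losses: dict          # term name -> loss value
    selected: str | None
    loss: float
    skipped: dict = field(default_factory=dict)


@dataclass
class SIECVTrace:
    direction: str
    cycles: list[CycleRecord]
    stopping_reason: str
    final_spec: ModelSpec
    final_iecv: IECVResult | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class GlobalModel:
    terms: list[str]
    unshrunken: dict
    shrinkage_slope: float
    intercept_correction: float
    shrunken: dict
    pooled_by_term: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


class StageOneCache:
    """Memoizes per-cluster Firth fits keyed by (term names, cluster)."""

    def __init__(self) -> None:
        self._fits: dict = {}

    def fit(self, data: ClusteredDataset, spec: ModelSpec, design,
            cluster) -> ClusterFit:
        key = (tuple(spec.term_names), cluster)
        if key not in self._fits:
            rows = data.frame[data.cluster_col] == cluster
            X = design.loc[rows.to_numpy()]
            y = data.outcome(cluster)
            fit = fit_firth(X, y, cluster=cluster)
            fit = reestimate_intercept(fit, X, y)
            self._fits[key] = fit
        return self._fits[key]


def _pool_coefficients(dev_fits: list[ClusterFit], term_names: list[str],
                       method: str) -> dict:
    """Term-wise univariate random-effects pooling across cluster fits."""
    coefficients = {}
    for term in term_names:
        pairs = [(f.coef()[term], dict(zip(f.terms, f.se))[term])
                 for f in dev_fits if term in f.terms]
        if len(pairs) < 2:
            raise EstimationError(
                f"term {term!r} estimable in fewer than 2 development "
                "clusters; cannot pool"
            )
        values, ses = zip(*pairs)
        coefficients[term] = pool(values, ses, method=method).value
    return coefficients


def iecv(data: ClusteredDataset, spec: ModelSpec, *,
         tau_estimator: str = "REML", alpha: float = 0.05,
         metrics: tuple = ALL_METRICS,
         c_stat_transform: str = "identity",
         centering: str = "within",
         intercept_strategy: str = "pooled",
         cache: StageOneCache | None = None) -> IECVResult:
    """Run one full internal-external cross-validation of ``spec``.

    Every cluster is held out once; development coefficients are the
    random-effects pooled stage-1 estimates of the other clusters (the
    hold-out cluster's data never touches them).  ``centering`` controls
    how square-after-centering terms are computed for hold-out rows:
    "within" (default) centers each cluster with its own means, as a
    deployed model would for a new cluster; "development" carries the grand
    mean of the development rows instead.
    """
    cache = cache or StageOneCache()
    warnings_: list[str] = []

    viable = [k for k in data.cluster_labels if data.fit_viable(k)]
    skipped_dev = [k for k in data.cluster_labels if k not in viable]
    for k in skipped_dev:
        msg = (f"cluster {k!r} has no events or no non-events; "
               "validation-only (excluded from development pooling)")
        warnings_.append(msg)
        logger.warning(msg)
    if len(viable) < 3:
        raise EstimationError(
            f"only {len(viable)} clusters usable for development; "
            "need >= 3 for meaningful pooling and prediction intervals"
        )

    design = build_design(data, spec)
    fits = {k: cache.fit(data, spec, design, k) for k in viable}

    holdouts: list[HoldoutEvaluation] = []
    for h in data.cluster_labels:
        dev_fits = [fits[k] for k in viable if k != h]
        coefficients = _pool_coefficients(
            dev_fits, [INTERCEPT] + [t.name for t in spec.included],
            tau_estimator,
        )
        rows = (data.frame[data.cluster_col] == h).to_numpy()
        if centering == "development" and any(t.is_centered
                                              for t in spec.included):
            dev_data = data.drop_cluster(h)
            means = cluster_center_means(dev_data, spec)
            grand = {src: float(np.mean(list(m.values())))
                     for src, m in means.items()}
            holdout_design = build_design(data, spec,
                                          center_means=grand).loc[rows]
        else:
            holdout_design = design.loc[rows]
        y_h = data.outcome(h)
        if intercept_strategy == "holdout_reestimated" and 0 < y_h.sum() < len(y_h):
            from .firth import solve_offset_intercept
            lp = (holdout_design[list(coefficients)].to_numpy()
                  @ np.fromiter(coefficients.values(), dtype=float))
            offset = lp - coefficients[INTERCEPT]
            a, _ = solve_offset_intercept(y_h, offset)
            coefficients = dict(coefficients)
            coefficients[INTERCEPT] = a
        if set(metrics) == {"mse"}:
            yhat = predict(coefficients, holdout_design)
            performance = {"mse": mse(y_h, yhat, cluster=h)}
        else:
            performance = all_metrics(y_h, coefficients, holdout_design,
                                      cluster=h)
            performance = {m: performance[m] for m in metrics}
        holdouts.append(HoldoutEvaluation(h, coefficients, performance))

    pooled: dict[str, PooledEstimate] = {}
    intervals: dict[str, PredictionInterval] = {}
    for metric in metrics:
        ests = [h.performance[metric] for h in holdouts
                if h.performance[metric].defined and h.performance[metric].se > 0]
        if len(ests) < 2:
            warnings_.append(f"metric {metric!r}: fewer than 2 defined "
                             "hold-out estimates; not pooled")
            continue
        values = [e.value for e in ests]
        ses = [e.se for e in ests]
        transform = (c_stat_transform if metric == "c_statistic"
                     else "identity")
        p = pool_transformed(values, ses, transform=transform,
                             method=tau_estimator, ci_level=1 - alpha)
        pooled[metric] = p
        intervals[metric] = prediction_interval(p, level=1 - alpha)

    return IECVResult(spec, holdouts, pooled, intervals, warnings_)


def interaction_guard(spec: ModelSpec, candidate: Term,
                      require_main_effects: bool = True) -> bool:
    """Is ``candidate`` eligible for inclusion under the main-effect rule?

    When the rule is on, an interaction may only enter once every
    constituent variable already appears as a non-interaction term.
    """
    if not require_main_effects or candidate.kind != "interaction":
        return True
    present = {src for t in spec.included if t.kind != "interaction"
               for src in t.sources}
    return all(src in present for src in candidate.sources)


def _locked_main_effects(spec: ModelSpec) -> set[str]:
    """Names of included non-interaction terms whose source feeds an
    included interaction (they must stay while the interaction stays)."""
    interacting = {src for t in spec.included if t.kind == "interaction"
                   for src in t.sources}
    return {t.name for t in spec.included
            if t.kind != "interaction"
            and any(src in interacting for src in t.sources)}


def _evaluate(data, spec, *, loss, lam, tau_estimator, centering,
              cache) -> AggregatedLoss:
    """Score one candidate model: IECV on the MSE, then the aggregated loss."""
    result = iecv(data, spec, tau_estimator=tau_estimator,
                  metrics=("mse",), centering=centering, cache=cache)
    estimates = result.metric_values("mse")
    return aggregate(estimates, loss, lam=lam, method=tau_estimator)


def _select(candidate_losses: dict) -> str:
    """Deterministic argmin: ties break toward earlier insertion order."""
    best = min(candidate_losses.values())
    ties = [name for name, v in candidate_losses.items() if v == best]
    if len(ties) > 1:
        logger.info("tie between %s; selecting %s", ties, ties[0])
    return ties[0]


def siecv(data: ClusteredDataset, spec: ModelSpec, *,
          loss: str = "re", lam: float = 0.5,
          tau_estimator: str = "REML",
          require_main_effects: bool = False,
          min_improvement: float = 0.0,
          centering: str = "within",
          c_stat_transform: str = "identity",
          alpha: float = 0.05) -> SIECVTrace:
    """Forward stepwise IECV predictor selection.

    Cycle 0 scores the base model (forced/included terms only).  Each later
    cycle scores every remaining candidate by a full IECV pass on the MSE,
    adds the argmin if it improves the aggregated loss, and stops otherwise.
    """
    cache = StageOneCache()
    kwargs = dict(loss=loss, lam=lam, tau_estimator=tau_estimator,
                  centering=centering, cache=cache)
    warnings_: list[str] = []

    base_loss = _evaluate(data, spec, **kwargs)
    cycles = [CycleRecord(0, {"<baseline>": base_loss.value}, "<baseline>",
                          base_loss.value)]
    current, current_loss = spec, base_loss.value
    n_candidates = len(spec.candidates)

    for i in range(1, n_candidates + 1):
        losses: dict[str, float] = {}
        skipped: dict[str, str] = {}
        for cand in current.candidates:
            if not interaction_guard(current, cand, require_main_effects):
                skipped[cand.name] = "main effects not yet included"
                continue
            try:
                losses[cand.name] = _evaluate(
                    data, current.with_candidate(cand), **kwargs).value
            except EstimationError as exc:
                skipped[cand.name] = str(exc)
                msg = f"cycle {i}: candidate {cand.name!r} skipped: {exc}"
                warnings_.append(msg)
                logger.warning(msg)
        if not losses:
            cycles.append(CycleRecord(i, {}, None, np.nan, skipped))
            return _finalize(data, current, cycles, "candidates_exhausted",
                             "forward", warnings_, cache, tau_estimator,
                             centering, c_stat_transform, alpha)
        chosen = _select(losses)
        if losses[chosen] >= current_loss - min_improvement:
            cycles.append(CycleRecord(i, losses, None, losses[chosen],
                                      skipped))
            return _finalize(data, current, cycles, "no_improvement",
                             "forward", warnings_, cache, tau_estimator,
                             centering, c_stat_transform, alpha)
        cycles.append(CycleRecord(i, losses, chosen, losses[chosen], skipped))
        term = next(t for t in current.candidates if t.name == chosen)
        current = current.with_candidate(term)
        current_loss = losses[chosen]
        if require_main_effects and term.kind == "interaction":
            mains = {t.name for t in current.included
                     if t.kind != "interaction"
                     and any(s in term.sources for s in t.sources)}
            current = current.force(mains)
        if not current.candidates:
            return _finalize(data, current, cycles, "candidates_exhausted",
                             "forward", warnings_, cache, tau_estimator,
                             centering, c_stat_transform, alpha)
    return _finalize(data, current, cycles, "candidates_exhausted", "forward",
                     warnings_, cache, tau_estimator, centering,
                     c_stat_transform, alpha)


def siecv_backward(data: ClusteredDataset, spec: ModelSpec, *,
                   loss: str = "re", lam: float = 0.5,
                   tau_estimator: str = "REML",
                   require_main_effects: bool = False,
                   min_improvement: float = 0.0,
                   centering: str = "within",
                   c_stat_transform: str = "identity",
                   alpha: float = 0.05) -> SIECVTrace:
    """Backward stepwise IECV: start full, remove the term whose removal
    most improves the aggregated loss, stop when no removal improves."""
    cache = StageOneCache()
    kwargs = dict(loss=loss, lam=lam, tau_estimator=tau_estimator,
                  centering=centering, cache=cache)
    warnings_: list[str] = []

    base_loss = _evaluate(data, spec, **kwargs)
    cycles = [CycleRecord(0, {"<full model>": base_loss.value},
                          "<full model>", base_loss.value)]
    current, current_loss = spec, base_loss.value
    n_removable = len([t for t in spec.included if t.name not in spec.forced])

    for i in range(1, n_removable + 1):
        locked = _locked_main_effects(current) if require_main_effects \
            else set()
        removable = [t for t in current.included
                     if t.name not in current.forced and t.name not in locked]
        losses: dict[str, float] = {}
        skipped: dict[str, str] = {}
        for term in removable:
            try:
                losses[term.name] = _evaluate(
                    data, current.without_term(term.name), **kwargs).value
            except EstimationError as exc:
                skipped[term.name] = str(exc)
                msg = f"cycle {i}: removal of {term.name!r} skipped: {exc}"
                warnings_.append(msg)
                logger.warning(msg)
        if not losses:
            cycles.append(CycleRecord(i, {}, None, np.nan, skipped))
            return _finalize(data, current, cycles, "candidates_exhausted",
                             "backward", warnings_, cache, tau_estimator,
                             centering, c_stat_transform, alpha)
        chosen = _select(losses)
        if losses[chosen] >= current_loss - min_improvement:
            cycles.append(CycleRecord(i, losses, None, losses[chosen],
                                      skipped))
            return _finalize(data, current, cycles, "no_improvement",
                             "backward", warnings_, cache, tau_estimator,
                             centering, c_stat_transform, alpha)
        cycles.append(CycleRecord(i, losses, chosen, losses[chosen], skipped))
        current = current.without_term(chosen)
        current_loss = losses[chosen]
    return _finalize(data, current, cycles, "candidates_exhausted",
                     "backward", warnings_, cache, tau_estimator, centering,
                     c_stat_transform, alpha)


def _finalize(data, spec, cycles, reason, direction, warnings_, cache,
              tau_estimator, centering, c_stat_transform,
              alpha) -> SIECVTrace:
    final = iecv(data, spec, tau_estimator=tau_estimator,
                 metrics=ALL_METRICS, centering=centering,
                 c_stat_transform=c_stat_transform, alpha=alpha, cache=cache)
    return SIECVTrace(direction, cycles, reason, spec, final, warnings_)


def fit_global(data: ClusteredDataset, spec: ModelSpec,
               final_iecv: IECVResult | None = None, *,
               tau_estimator: str = "REML",
               cache: StageOneCache | None = None) -> GlobalModel:
    """Fit the final model on all clusters (no hold-out) with shrinkage.

    Pools all K stage-1 fits term-wise.  If a final-cycle IECV result is
    supplied, slopes are multiplied by its summary calibration slope and
    the summary calibration-in-the-large is added to the intercept; without
    one, the shrinkage factors default to the identity (s = 1, a = 0).
    """
    cache = cache or StageOneCache()
    viable = [k for k in data.cluster_labels if data.fit_viable(k)]
    if len(viable) < 2:
        raise EstimationError("need >= 2 fit-viable clusters")
    design = build_design(data, spec)
    fits = [cache.fit(data, spec, design, k) for k in viable]
    term_names = [INTERCEPT] + [t.name for t in spec.included]
    pooled_by_term = {}
    for term in term_names:
        pairs = [(f.coef()[term], dict(zip(f.terms, f.se))[term])
                 for f in fits if term in f.terms]
        if len(pairs) < 2:
            raise EstimationError(f"term {term!r} estimable in < 2 clusters")
        values, ses = zip(*pairs)
        pooled_by_term[term] = pool(values, ses, method=tau_estimator)
    unshrunken = {t: p.value for t, p in pooled_by_term.items()}

    s, a = 1.0, 0.0
    if final_iecv is not None:
        if "cal_slope" in final_iecv.pooled:
            s = final_iecv.pooled["cal_slope"].value
        if "cal_in_large" in final_iecv.pooled:
            a = final_iecv.pooled["cal_in_large"].value
    shrunken = {t: (v * s if t != INTERCEPT else v + a)
                for t, v in unshrunken.items()}
    return GlobalModel(
        terms=term_names, unshrunken=unshrunken, shrinkage_slope=s,
        intercept_correction=a, shrunken=shrunken,
        pooled_by_term=pooled_by_term,
        provenance={"tau_estimator": tau_estimator,
                    "clusters_pooled": viable},
    )
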