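"""Aggregated loss functions quantifying model generalizability.

Each loss collapses the K hold-out performance estimates (one per cluster)
into a single number that the stepwise selection minimizes.  They differ in
how much weight they put on *average* performance versus its
*between-cluster heterogeneity*:

* ``A_M`` — unweighted mean; ignores clustering and uncertainty entirely.
* ``A_RE(lambda)`` — lambda * (random-effects pooled mean) +
  (1 - lambda) * tau-hat, where tau-hat is the between-cluster SD of the
  statistic from the same meta-analysis.  lambda = 1 optimizes the average
  alone, lambda = 0 optimizes heterogeneity alone, lambda = 1/2 weights
  them equally.
* ``A_SD`` — sample SD (K - 1 denominator) of the K estimates.
* ``A_Gini`` — Gini mean difference, 2/(K(K-1)) * sum of absolute pairwise
  differences; a nonparametric dispersion measure.

All are defined on the hold-out MSE by default (a loss to minimize); when
applied to other metrics the caller owns the direction of optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EstimationError
from .meta import PooledEstimate, pool
from .performance import PerformanceEstimate

LOSS_FAMILIES = ("mean", "re", "sd", "gini")


@dataclass
class AggregatedLoss:
    family: str
    value: float
    lam: float | None = None       # only for the "re" family
    components: dict = field(default_factory=dict)
    estimates: list[PerformanceEstimate] = field(default_factory=list)


def _values(perf: list[PerformanceEstimate]) -> np.ndarray:
    if len(perf) < 2:
        raise EstimationError("aggregated losses need >= 2 cluster estimates")
    vals = np.array([p.value for p in perf], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise EstimationError("undefined performance estimate in loss input")
    return vals


def loss_mean(perf: list[PerformanceEstimate]) -> AggregatedLoss:
    vals = _values(perf)
    return AggregatedLoss("mean", float(vals.mean()), estimates=list(perf))


def loss_re(perf: list[PerformanceEstimate], lam: float,
            method: str = "REML") -> AggregatedLoss:
    """lambda * pooled mean + (1 - lambda) * tau-hat (SD scale, not tau^2)."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError(f"lambda must be in [0, 1], got {lam}")
    vals = _values(perf)
    ses = np.array([p.se for p in perf], dtype=float)
    pooled: PooledEstimate = pool(vals, ses, method=method)
    value = lam * pooled.value + (1.0 - lam) * pooled.tau
    return AggregatedLoss(
        "re", float(value), lam=lam,
        components={"pooled": pooled.value, "tau": pooled.tau,
                    "method": pooled.method, "fallback": pooled.fallback},
        estimates=list(perf),
    )


def loss_sd(perf: list[PerformanceEstimate]) -> AggregatedLoss:
    vals = _values(perf)
    return AggregatedLoss("sd", float(vals.std(ddof=1)), estimates=list(perf))


def loss_gini(perf: list[PerformanceEstimate]) -> AggregatedLoss:
    """Gini mean difference over all ordered pairs; O(K log K) via sorting."""
    vals = np.sort(_values(perf))
    k = len(vals)
    # sum_{i<j} (v_j - v_i) = sum_j v_j (2j - k + 1) for sorted v, 0-indexed
    idx = np.arange(k)
    pair_sum = float(np.sum(vals * (2 * idx - k + 1)))
    return AggregatedLoss("gini", 2.0 * pair_sum / (k * (k - 1)),
                          estimates=list(perf))


def aggregate(perf: list[PerformanceEstimate], family: str,
              lam: float = 0.5, method: str = "REML") -> AggregatedLoss:
    """Dispatch on the configured loss family."""
    if family == "mean":
        return loss_mean(perf)
    if family == "re":
        return loss_re(perf, lam, method=method)
    if family == "sd":
        return loss_sd(perf)
    if family == "gini":
        return loss_gini(perf)
    raise ConfigurationError(
        f"unknown loss family {family!r}; use one of {LOSS_FAMILIES}"
    )
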