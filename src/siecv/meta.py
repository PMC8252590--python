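"""Univariate fixed- and random-effects meta-analysis.

Pools per-cluster estimates (regression coefficients or hold-out performance
statistics) under the two-level normal model

    est_k ~ N(theta_k, se_k^2),   theta_k ~ N(mu, tau^2),

with inverse-variance weights w_k = 1 / (se_k^2 + tau^2).  Between-cluster
variance tau^2 is estimated by DerSimonian-Laird (method of moments on
Cochran's Q), Paule-Mandel (fixed point of the generalized Q equation), or
REML (bounded 1-D restricted-likelihood maximization); FE forces tau^2 = 0.

Confidence intervals use the Hartung-Knapp variance

    var_HK = [ sum w_k (est_k - mu)^2 / (Q - 1) ] / sum w_k

with a t_{Q-1} quantile; the approximate prediction interval for the value
in a new cluster is mu +/- t_{Q-2} sqrt(tau^2 + var(mu)) with the
conventional variance var(mu) = 1 / sum w_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import DataValidationError, EstimationError

METHODS = ("DL", "PM", "REML", "FE")

PM_TOL = 1e-8
PM_MAX_ITER = 100


@dataclass
class PredictionInterval:
    level: float
    lower: float
    upper: float
    defined: bool = True


@dataclass
class PooledEstimate:
    """Random-effects summary of one quantity across clusters."""

    value: float
    tau2: float
    var_conventional: float
    var_hk: float
    weights: np.ndarray
    q: int                      # number of estimates pooled
    method: str                 # estimator actually used
    fallback: bool = False      # True if REML fell back to DL
    ci_level: float = 0.95
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    transform: str = "identity"
    notes: dict = field(default_factory=dict)

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau2))

    @property
    def se_hk(self) -> float:
        return float(np.sqrt(self.var_hk))


def _dl_tau2(values: np.ndarray, variances: np.ndarray) -> float:
    w = 1.0 / variances
    mu_fe = float(w @ values / w.sum())
    q_stat = float(w @ (values - mu_fe) ** 2)
    df = len(values) - 1
    c = float(w.sum() - (w ** 2).sum() / w.sum())
    if c <= 0:
        return 0.0
    return max(0.0, (q_stat - df) / c)


def _pm_tau2(values: np.ndarray, variances: np.ndarray) -> float:
    df = len(values) - 1

    def gen_q(tau2: float) -> float:
        w = 1.0 / (variances + tau2)
        mu = float(w @ values / w.sum())
        return float(w @ (values - mu) ** 2) - df

    if gen_q(0.0) <= 0:
        return 0.0
    hi = float(np.var(values, ddof=1)) * 10 + variances.max()
    it = 0
    while gen_q(hi) > 0 and it < PM_MAX_ITER:
        hi *= 2
        it += 1
    return float(optimize.brentq(gen_q, 0.0, hi, xtol=PM_TOL,
                                 maxiter=PM_MAX_ITER * 10))


def _reml_tau2(values: np.ndarray, variances: np.ndarray) -> float:
    hi = max(10.0 * float(np.var(values, ddof=1)), 1e-8)

    def nll(tau2: float) -> float:
        v = variances + tau2
        w = 1.0 / v
        mu = float(w @ values / w.sum())
        return 0.5 * (np.log(v).sum() + np.log(w.sum())
                      + float(w @ (values - mu) ** 2))

    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success or not np.isfinite(res.fun):
        raise EstimationError("REML did not converge")
    return float(res.x)


def pool(values, ses, method: str = "REML", ci_level: float = 0.95,
         reml_fallback: str = "DL") -> PooledEstimate:
    """Pool >= 2 (value, SE) pairs into a random-effects summary.

    REML non-convergence falls back to DerSimonian-Laird with a warning and
    the ``fallback`` flag set, so the estimator actually used is always
    recorded in the result.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(values) < 2:
        raise EstimationError("need at least 2 estimates to pool")
    if len(values) != len(ses):
        raise EstimationError("values and SEs have different lengths")
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)):
        raise EstimationError("all SEs must be positive and finite")
    if method not in METHODS:
        raise EstimationError(f"unknown estimator {method!r}; use {METHODS}")
    variances = ses ** 2

    used, fallback = method, False
    if np.allclose(values, values[0]):
        tau2 = 0.0  # degenerate: no dispersion, all estimators agree
    elif method == "FE":
        tau2 = 0.0
    elif method == "DL":
        tau2 = _dl_tau2(values, variances)
    elif method == "PM":
        tau2 = _pm_tau2(values, variances)
    else:
        try:
            tau2 = _reml_tau2(values, variances)
        except EstimationError:
            warnings.warn("REML non-convergence; falling back to DL",
                          RuntimeWarning, stacklevel=2)
            tau2 = _dl_tau2(values, variances)
            used, fallback = reml_fallback, True

    w = 1.0 / (variances + tau2)
    mu = float(w @ values / w.sum())
    var_conv = float(1.0 / w.sum())
    q = len(values)
    var_hk = float((w @ (values - mu) ** 2) / (q - 1) / w.sum())
    t_crit = float(stats.t.ppf(0.5 + ci_level / 2, q - 1))
    half = t_crit * np.sqrt(var_hk)
    return PooledEstimate(
        value=mu, tau2=tau2, var_conventional=var_conv, var_hk=var_hk,
        weights=w, q=q, method=used, fallback=fallback, ci_level=ci_level,
        ci_lower=mu - half, ci_upper=mu + half,
    )


def prediction_interval(pooled: PooledEstimate,
                        level: float = 0.95) -> PredictionInterval:
    """Approximate interval for the quantity's value in a new cluster.

    Undefined (flagged, not raised) when fewer than 3 estimates were pooled,
    since the t reference has Q - 2 degrees of freedom.
    """
    if pooled.q < 3:
        return PredictionInterval(level, np.nan, np.nan, defined=False)
    t_crit = float(stats.t.ppf(0.5 + level / 2, pooled.q - 2))
    half = t_crit * np.sqrt(pooled.tau2 + pooled.var_conventional)
    lo, hi = pooled.value - half, pooled.value + half
    if pooled.transform == "logit":
        lo, hi = float(expit(lo)), float(expit(hi))
    return PredictionInterval(level, lo, hi)


def pool_transformed(values, ses, transform: str = "identity",
                     method: str = "REML",
                     ci_level: float = 0.95) -> PooledEstimate:
    """Pool on a transformed scale and back-transform the summary.

    For ``logit`` (bounded statistics such as the c-statistic), values must
    lie strictly in (0, 1); delta-method SEs are SE / (v (1 - v)).  The
    pooled value and CI are returned on the original scale; tau^2 stays on
    the transformed scale.
    """
    if transform == "identity":
        return pool(values, ses, method=method, ci_level=ci_level)
    if transform != "logit":
        raise EstimationError(f"unknown transform {transform!r}")
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any((values <= 0) | (values >= 1)):
        raise DataValidationError(
            "logit pooling requires values strictly in (0, 1)"
        )
    tvals = logit(values)
    tses = ses / (values * (1 - values))
    pooled = pool(tvals, tses, method=method, ci_level=ci_level)
    pooled.transform = "logit"
    pooled.notes["value_logit"] = pooled.value
    pooled.value = float(expit(pooled.value))
    pooled.ci_lower = float(expit(pooled.ci_lower))
    pooled.ci_upper = float(expit(pooled.ci_upper))
    return pooled


def forest_rows(labels, values, ses, pooled: PooledEstimate,
                pi: PredictionInterval | None = None,
                z_level: float = 0.95) -> list[dict]:
    """Tidy rows for a forest plot: clusters, summary, prediction interval."""
    z = float(stats.norm.ppf(0.5 + z_level / 2))
    total_w = float(np.sum(pooled.weights))
    rows = []
    for lab, v, s, w in zip(labels, values, ses, pooled.weights):
        rows.append({
            "label": str(lab), "estimate": float(v),
            "lower": float(v - z * s), "upper": float(v + z * s),
            "weight_pct": 100.0 * float(w) / total_w,
            "is_summary": False, "is_pi": False,
        })
    rows.append({
        "label": "Summary", "estimate": pooled.value,
        "lower": pooled.ci_lower, "upper": pooled.ci_upper,
        "weight_pct": 100.0, "is_summary": True, "is_pi": False,
    })
    if pi is not None and pi.defined:
        rows.append({
            "label": "Prediction interval", "estimate": pooled.value,
            "lower": pi.lower, "upper": pi.upper,
            "weight_pct": float("nan"), "is_summary": False, "is_pi": True,
        })
    return rows
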