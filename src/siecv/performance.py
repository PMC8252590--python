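"""Hold-out-cluster performance statistics for probability predictions.

Four metrics, each returned with a standard error so that the per-cluster
estimates can be pooled meta-analytically:

* ``mse`` — mean squared error of predicted probabilities (the Brier score
  for a binary outcome); SE is the sampling SD of the squared errors over
  sqrt(n).
* ``calibration_slope`` — slope from a Firth-penalized logistic regression
  of the outcome on the model's linear predictor; 1 means the linear
  predictor is correctly scaled, < 1 means predictions are too extreme.
* ``calibration_in_the_large`` — intercept of an unpenalized logistic model
  with the linear predictor as a fixed offset (the standard recalibration
  framework); 0 means predicted and observed overall risk agree, positive
  values mean observed risk exceeds predicted.
* ``c_statistic`` — probability that a random case is ranked above a random
  control (ties count 1/2), computed exactly via midranks; SE by
  Hanley-McNeil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .errors import DataValidationError, EstimationError
from .firth import fit_firth, solve_offset_intercept

MIN_CLASS_FOR_FIT = 2  # events/non-events needed before fitting slope/CIL


@dataclass
class PerformanceEstimate:
    metric: str
    cluster: object
    value: float
    se: float
    n: int
    events: int
    defined: bool = True
    notes: dict = field(default_factory=dict)


def predict(coefficients: dict, design: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities expit(X b) for named coefficients.

    The coefficient names must match the design columns exactly — a
    mismatch means the model and design were built from different term
    sets, which is a programming error worth failing loudly on.
    """
    missing = set(coefficients) - set(design.columns)
    extra = set(design.columns) - set(coefficients)
    if missing or extra:
        raise DataValidationError(
            f"coefficient/design mismatch; missing columns {sorted(missing)},"
            f" unmatched columns {sorted(extra)}"
        )
    X = design[list(coefficients)].to_numpy(dtype=float)
    beta = np.fromiter(coefficients.values(), dtype=float)
    return expit(X @ beta)


def linear_predictor(coefficients: dict, design: pd.DataFrame) -> np.ndarray:
    X = design[list(coefficients)].to_numpy(dtype=float)
    beta = np.fromiter(coefficients.values(), dtype=float)
    return X @ beta


def _as_arrays(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise DataValidationError("y and predictions differ in length")
    if len(y) < 2:
        raise DataValidationError("need at least 2 observations")
    return y, yhat


def mse(y, yhat, cluster=None) -> PerformanceEstimate:
    """Brier score: mean((y - yhat)^2) with SE = SD(squared errors)/sqrt(n)."""
    y, yhat = _as_arrays(y, yhat)
    sq = (y - yhat) ** 2
    return PerformanceEstimate(
        metric="mse", cluster=cluster, value=float(sq.mean()),
        se=float(sq.std(ddof=1) / np.sqrt(len(sq))),
        n=len(y), events=int(y.sum()),
    )


def _fit_viable(y) -> bool:
    events = int(np.sum(y))
    return events >= MIN_CLASS_FOR_FIT and len(y) - events >= MIN_CLASS_FOR_FIT


def calibration_slope(y, lp, cluster=None) -> PerformanceEstimate:
    """Firth-penalized logistic regression of y on the linear predictor."""
    y, lp = _as_arrays(y, lp)
    if np.ptp(lp) == 0:
        raise EstimationError(
            "constant linear predictor; calibration slope unidentifiable"
        )
    if not _fit_viable(y):
        return PerformanceEstimate(
            "cal_slope", cluster, np.nan, np.nan, len(y), int(y.sum()),
            defined=False, notes={"reason": "too few events or non-events"},
        )
    X = pd.DataFrame({"(Intercept)": np.ones(len(y)), "lp": lp})
    fit = fit_firth(X, y)
    j = fit.terms.index("lp")
    return PerformanceEstimate(
        "cal_slope", cluster, float(fit.estimates[j]), float(fit.se[j]),
        len(y), int(y.sum()),
    )


def calibration_in_the_large(y, lp, cluster=None) -> PerformanceEstimate:
    """Intercept of the offset-recalibration model logit(p) = a + lp.

    Positive values mean observed risk runs higher than predicted.  If the
    unpenalized offset model fails (separation-like degeneracy), the value
    falls back to a Firth fit with the slope fixed at 1 via offset-free
    approximation and the result is flagged.
    """
    y, lp = _as_arrays(y, lp)
    if not _fit_viable(y):
        return PerformanceEstimate(
            "cal_in_large", cluster, np.nan, np.nan, len(y), int(y.sum()),
            defined=False, notes={"reason": "too few events or non-events"},
        )
    try:
        a, se_a = solve_offset_intercept(y, lp)
        notes = {}
    except EstimationError:
        # Firth-penalized 1-parameter fit on the shifted outcome scale
        X = pd.DataFrame({"(Intercept)": np.ones(len(y))})
        fit = fit_firth(X, y)
        a = float(fit.estimates[0]) - float(np.mean(lp))
        se_a = float(fit.se[0])
        notes = {"fallback": "firth_intercept"}
    return PerformanceEstimate(
        "cal_in_large", cluster, float(a), float(se_a),
        len(y), int(y.sum()), notes=notes,
    )


def c_statistic(y, yhat, cluster=None,
                se_method: str = "hanley-mcneil") -> PerformanceEstimate:
    """Concordance probability P(yhat_case > yhat_control) + P(tie)/2.

    Computed exactly with midranks (equivalent to brute-force pair
    counting).  SE by the Hanley-McNeil closed form by default; "delong"
    computes the DeLong variance instead.
    """
    y, yhat = _as_arrays(y, yhat)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return PerformanceEstimate(
            "c_statistic", cluster, np.nan, np.nan, len(y), n1,
            defined=False, notes={"reason": "one outcome class absent"},
        )
    ranks = rankdata(yhat)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    if se_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc ** 2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
               + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
        var = max(var, 0.0)
    elif se_method == "delong":
        cases = yhat[y == 1]
        controls = yhat[y == 0]
        # placement values
        v10 = np.array([
            (np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n0
            for c in cases
        ])
        v01 = np.array([
            (np.sum(cases > c) + 0.5 * np.sum(cases == c)) / n1
            for c in controls
        ])
        var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    else:
        raise EstimationError(f"unknown c-statistic SE method {se_method!r}")
    return PerformanceEstimate(
        "c_statistic", cluster, float(auc), float(np.sqrt(var)),
        len(y), n1, notes={"se_method": se_method},
    )


def all_metrics(y, coefficients: dict, design: pd.DataFrame,
                cluster=None) -> dict[str, PerformanceEstimate]:
    """Compute every supported metric for one hold-out cluster."""
    lp = linear_predictor(coefficients, design)
    yhat = expit(lp)
    out = {"mse": mse(y, yhat, cluster)}
    y_arr = np.asarray(y, dtype=float)
    if np.ptp(lp) > 0:
        out["cal_slope"] = calibration_slope(y_arr, lp, cluster)
    else:
        out["cal_slope"] = PerformanceEstimate(
            "cal_slope", cluster, np.nan, np.nan, len(y_arr),
            int(y_arr.sum()), defined=False,
            notes={"reason": "constant linear predictor"},
        )
    out["cal_in_large"] = calibration_in_the_large(y_arr, lp, cluster)
    out["c_statistic"] = c_statistic(y_arr, yhat, cluster)
    return out
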