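"""Published worked-example tables bundled for demonstrations and checks.

Both tables come from an 11-study individual-participant-data meta-analysis
on the diagnosis of deep vein thrombosis (N = 10 014): per-study
Firth-penalized logistic coefficients for a three-predictor model, and the
per-hold-out-cluster IECV performance of the same model.  Only the printed
per-study (estimate, SE) pairs are bundled — the participant-level data are
restricted — which is exactly enough to exercise the second stage of the
two-stage approach: pooling printed per-cluster estimates reproduces the
published summary rows.
"""

from __future__ import annotations

import pandas as pd

# per-study logistic coefficients (estimate, SE), 11 studies
_DVT_COEFFICIENTS = [
    # cluster, intercept, se, malignancy, se, calf_difference, se, surgery, se
    (1, -2.46, 0.14, 0.90, 0.33, 1.17, 0.19, 0.04, 0.35),
    (2, -0.95, 0.11, 0.31, 0.24, 0.98, 0.15, 0.17, 0.25),
    (3, -2.92, 0.44, 1.57, 0.87, 1.59, 0.50, 1.73, 0.54),
    (4, -1.92, 0.09, 0.63, 0.16, 1.68, 0.13, 0.83, 0.17),
    (5, -2.27, 0.16, 0.24, 0.42, 1.03, 0.20, 0.52, 0.26),
    (6, -2.25, 0.12, 1.23, 0.30, 1.40, 0.17, 0.51, 0.21),
    (7, -3.18, 0.13, 1.69, 0.22, 1.41, 0.19, 0.26, 0.31),
    (8, -1.72, 0.18, 1.02, 0.58, 1.24, 0.27, 0.78, 0.51),
    (9, -2.01, 0.11, 0.80, 0.25, 1.25, 0.14, 0.37, 0.19),
    (10, -2.16, 0.18, 1.04, 0.46, 0.65, 0.34, 0.79, 0.35),
    (11, -2.30, 0.19, 1.65, 0.26, 1.32, 0.23, 0.82, 0.27),
]

# per-hold-out-cluster IECV performance (estimate, SE), same 11 studies
_DVT_IECV_PERFORMANCE = [
    # cluster, cal_slope, se, cal_in_large, se, c_statistic, se
    (1, 0.86, 0.15, -0.44, 0.10, 0.65, 0.02),
    (2, 0.63, 0.11, 1.06, 0.08, 0.63, 0.02),
    (3, 1.49, 0.35, -0.24, 0.22, 0.78, 0.05),
    (4, 1.18, 0.10, 0.43, 0.06, 0.72, 0.01),
    (5, 0.73, 0.15, -0.33, 0.10, 0.65, 0.02),
    (6, 1.12, 0.14, -0.00, 0.08, 0.70, 0.02),
    (7, 1.24, 0.14, -0.93, 0.09, 0.71, 0.02),
    (8, 1.02, 0.24, 0.51, 0.13, 0.67, 0.03),
    (9, 0.92, 0.11, 0.12, 0.07, 0.68, 0.02),
    (10, 0.71, 0.27, -0.09, 0.14, 0.62, 0.04),
    (11, 1.27, 0.17, 0.15, 0.11, 0.74, 0.03),
]

# published summary rows (random-effects pooled values) for reference
DVT_PUBLISHED_SUMMARY = {
    "(Intercept)": -2.17,
    "malignancy": 0.98,
    "calf_difference": 1.27,
    "surgery": 0.55,
    "cal_slope": 1.00,
    "cal_in_large": 0.03,
    "c_statistic": 0.68,
}


def dvt_cluster_coefficients() -> pd.DataFrame:
    """Long-format per-study coefficients: cluster, term, estimate, se."""
    rows = []
    terms = ["(Intercept)", "malignancy", "calf_difference", "surgery"]
    for rec in _DVT_COEFFICIENTS:
        cluster = rec[0]
        for j, term in enumerate(terms):
            rows.append({"cluster": cluster, "term": term,
                         "estimate": rec[1 + 2 * j], "se": rec[2 + 2 * j]})
    return pd.DataFrame(rows)


def dvt_iecv_performance() -> pd.DataFrame:
    """Long-format per-hold-out-cluster IECV performance estimates."""
    rows = []
    metrics = ["cal_slope", "cal_in_large", "c_statistic"]
    for rec in _DVT_IECV_PERFORMANCE:
        cluster = rec[0]
        for j, metric in enumerate(metrics):
            rows.append({"cluster": cluster, "metric": metric,
                         "estimate": rec[1 + 2 * j], "se": rec[2 + 2 * j]})
    return pd.DataFrame(rows)
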