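# siecv — stepwise internal-external cross-validation for prediction models

`siecv` develops binary-outcome clinical prediction models on **clustered
individual-participant data** — multiple studies, centres, registries, or
regions pooled into one table — in a way that confronts, rather than hides,
the between-cluster heterogeneity that usually makes such models need local
recalibration.

## The problem and the method

A model developed by pooling clusters naively can look excellent on average
and still perform erratically in any *particular* setting, because both the
predictor–outcome associations and the baseline risk differ across
clusters. Internal-external cross-validation (IECV) makes this visible
during development: each of the K clusters is held out once, a model is
built on the remaining K − 1, and its performance in the hold-out cluster
is recorded. The K hold-out estimates are then combined by random-effects
meta-analysis, giving both a summary performance and a between-cluster
heterogeneity estimate τ̂ with a prediction interval for performance in a
*new* cluster.

Model development is two-stage: a Firth-penalized logistic regression

  logit P(y = 1) = α_k + Σ_p β_{p,k} x_p

is fitted once per cluster k (the Jeffreys-prior penalty keeps estimates
finite in small or separated clusters; the intercept is then re-estimated
unpenalized so fitted risk matches observed incidence), and for every
hold-out cluster the remaining clusters' coefficients are pooled term-wise
by univariate random-effects meta-analysis, with inverse-variance weights
w_k = 1/(SE_k² + τ̂²), Hartung–Knapp confidence intervals, and the
approximate prediction interval μ̂ ± t_{Q−2} √(τ̂² + var(μ̂)).

**Stepwise IECV (SIECV)** turns this into a predictor-selection rule. Each
candidate term is scored by a full IECV pass on the hold-out mean squared
error (Brier score), and the K hold-out MSEs are collapsed into one
aggregated loss Â:

| loss          | definition                         | optimizes |
|---------------|------------------------------------|-----------|
| `mean`        | unweighted mean of the K MSEs      | average performance, ignoring clustering |
| `re`, λ       | λ·Ẑ^RE + (1 − λ)·τ̂                | weighted blend of pooled average (λ = 1) and heterogeneity (λ = 0) |
| `sd`          | sample SD of the K MSEs            | stability across clusters |
| `gini`        | Gini mean difference of the K MSEs | stability, nonparametric |

The greedy loop adds (or, backward, removes) the argmin term each cycle and
stops as soon as the best candidate no longer improves Â. The final *global
model* is refit on all clusters and shrunken for selection-induced
optimism: slopes are multiplied by the summary calibration slope and the
summary calibration-in-the-large is added to the intercept.

## Worked example

Eight synthetic clusters of 300 participants with two real predictors
(a continuous biomarker, log-odds ratio 0.9, and a binary comorbidity,
log-odds ratio 0.6, both mildly heterogeneous across clusters) and one
pure-noise candidate:

```python
from siecv import (GeneratorConfig, PredictorSpec, generate, ModelSpec,
                   main_term, siecv, fit_global)

cfg = GeneratorConfig(
    K=8, cluster_sizes=300, mu_alpha=-1.2, sigma_alpha=0.3,
    predictors=(
        PredictorSpec("biomarker", mu_beta=0.9, tau=0.1, kind="continuous"),
        PredictorSpec("comorbidity", mu_beta=0.6, tau=0.1, prevalence=0.25),
        PredictorSpec("noise", mu_beta=0.0, tau=0.0, kind="continuous"),
    ),
    seed=7,
)
data, truth = generate(cfg)
spec = ModelSpec([], set(), [main_term("biomarker"),
                             main_term("comorbidity"), main_term("noise")])
trace = siecv(data, spec, loss="re", lam=0.5, tau_estimator="DL")
```

which prints (via the trace and final IECV):

```
cycle 0: losses={'<baseline>': 0.1084} selected=<baseline>
cycle 1: losses={'biomarker': 0.0912, 'comorbidity': 0.1077, 'noise': 0.1085} selected=biomarker
cycle 2: losses={'comorbidity': 0.0894, 'noise': 0.0912} selected=comorbidity
cycle 3: losses={'noise': 0.0894} selected=None
stopping reason: no_improvement
final terms: ['(Intercept)', 'biomarker', 'comorbidity']
mse: 0.172 (95% CI 0.161 to 0.183; 95% PI 0.152 to 0.192)
cal_slope: 0.986 (95% CI 0.829 to 1.142; 95% PI 0.768 to 1.203)
cal_in_large: 0.004 (95% CI -0.270 to 0.277; 95% PI -0.732 to 0.740)
c_statistic: 0.727 (95% CI 0.701 to 0.753; 95% PI 0.697 to 0.757)
```

Both true predictors enter (biomarker first — the larger effect), the
noise term is refused, and the loop stops by the no-improvement rule. The
pooled calibration slope near 1 and calibration-in-the-large near 0 say
the selected model transports well on average; the prediction intervals
say how much a new cluster might deviate. `fit_global` then yields the
deployable model:

```
shrinkage slope: 0.986 intercept correction: 0.004
shrunken coefficients: {'(Intercept)': -1.294, 'biomarker': 0.845, 'comorbidity': 0.628}
```

## Command line

```bash
siecv simulate --config gen.yaml --out data.csv --truth truth.json
siecv run      --data data.csv --config run.yaml --out results/
siecv validate --data data.csv --config run.yaml --out results/   # fixed-spec IECV
siecv report   --trace results/trace.json
```

`run` writes `trace.json` (per-cycle candidate losses and selections),
`final_model.json` (unshrunken and shrunken coefficients), per-metric
forest tables (TSV: cluster rows, summary row, prediction-interval row),
and `report.json`. Exit codes: 0 success, 2 configuration error, 3 data
validation error, 4 estimation failure.

## Bundled worked-example tables

`siecv.datasets` ships the published per-study (estimate, SE) tables of an
11-study deep-vein-thrombosis diagnostic IPD meta-analysis (N = 10 014):
per-study Firth logistic coefficients for a three-predictor model
(malignancy history, calf-circumference difference ≥ 3 cm, recent surgery)
and the per-hold-out-cluster IECV performance of that model. The
participant-level data are restricted, but the printed per-study estimates
are exactly what the second stage of the two-stage approach consumes.

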