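# Methods

This note records the statistical model, the estimation choices, and the
design decisions behind `siecv`, at the level a maintainer or reviewer
needs to judge what the package computes and what its tests do and do not
establish.

## Model and two-stage estimation

Participants j = 1..N are grouped in clusters k = 1..K (studies, centres,
regions). The outcome is binary and modelled cluster-specifically:

    logit P(y_{k,j} = 1) = α_k + Σ_p β_{p,k} x_{p,k,j}.

Estimation is two-stage. Stage 1 fits this model in each cluster alone;
stage 2 summarizes each coefficient across clusters with a univariate
random-effects meta-analysis (normal within- and between-cluster levels).
The two-stage route is what makes stepwise search affordable: a cluster's
fit depends only on its own rows and the current term set, so during IECV
each cluster is fitted once per candidate model and the K hold-out
evaluations merely recombine cached fits. The one-stage (mixed-model)
alternative and multivariate coefficient pooling are out of scope by
design; with all coefficients estimable in every cluster, univariate
pooling is the standard practice this package follows.

### Stage 1: Firth-penalized logistic regression

Small clusters and rare predictors produce separation, under which plain
maximum likelihood diverges. Stage 1 therefore maximizes the
Jeffreys-penalized likelihood l(β) + ½ log det I(β) (Newton–Raphson on the
modified score with step-halving; convergence when max |score| < 1e-6 and
max parameter change < 1e-6, cap 100 iterations — the algorithmic details
are this package's choice). Slope SEs come from the inverse penalized
information at the optimum. Because the penalty also shrinks the
intercept — biasing average predicted risk — the intercept is re-estimated
post hoc by unpenalized ML with the rest of the linear predictor as a
fixed offset. After re-estimation, mean fitted risk equals the observed
event rate exactly (the intercept score equation). The intercept's
reported SE is the offset-model SE, i.e. the SE of the estimation actually
performed; this is flagged in the fit's metadata since one could argue for
other conventions. Plain ML is available (`penalized=False`) for large
clusters.

### Stage 2: random-effects pooling

For one coefficient (or performance statistic) with per-cluster estimates
and SEs, between-cluster variance τ² is estimated by:

* **DL** — DerSimonian–Laird, method of moments on Cochran's Q;
* **PM** — Paule–Mandel, Brent root-finding of the generalized-Q equation
  (tolerance 1e-8);
* **REML** — bounded scalar maximization of the restricted likelihood on
  τ² ∈ [0, 10·var(estimates)];
* **FE** — τ² ≡ 0.

The default is REML with an automatic, flagged fallback to DL when REML
fails — the estimator actually used is always recorded. Weights are
w_k = 1/(SE_k² + τ̂²), the pooled value is Σw·est/Σw, and confidence
intervals use the Hartung–Knapp variance with a t_{Q−1} quantile (the
plain HK variant; no truncation). The approximate prediction interval for
the value in a new cluster is μ̂ ± t_{Q−2}√(τ̂² + var(μ̂)) with the
conventional variance; it is flagged undefined when fewer than 3 estimates
were pooled. Q is always the count of estimates actually pooled (K − 1
inside a development pool, K when pooling hold-out performances). Bounded
statistics can be pooled on the logit scale with delta-method SEs;
c-statistics default to the identity scale, matching how the bundled
worked-example tables print them.

## Hold-out performance

Predictions for a hold-out cluster use the pooled (mean) coefficients,
including the pooled intercept; re-estimating the intercept on the
hold-out cluster is available as an option but off by default, since a
deployed model has no outcome data from a new setting. Metrics:

* **MSE / Brier score** — mean squared error of predicted probabilities;
  SE = SD(squared errors)/√n.
* **Calibration slope** — slope of a Firth logistic regression of y on the
  linear predictor; 1 = correctly scaled, < 1 = predictions too extreme.
* **Calibration-in-the-large** — intercept of the unpenalized
  offset-recalibration model logit(p) = a + lp. The sign convention is
  positive = observed risk above predicted. Defined this way (rather than
  as a difference of mean logits) because it is the estimand of the
  standard recalibration framework; the choice is flagged in output
  metadata.
* **c-statistic** — exact midrank concordance (ties ½); SE by
  Hanley–McNeil in closed form, DeLong behind a flag.

Clusters with fewer than 2 events or 2 non-events get flagged, undefined
slope/CIL values (the fits are unstable); MSE and the c-statistic are
still computed when defined.

## Aggregated losses and the stepwise loop

The selection loss collapses the K hold-out MSEs: `mean` (unweighted
average), `re` with λ ∈ [0, 1] (λ·pooled + (1 − λ)·τ̂ — note τ̂ on the SD
scale, not τ̂²), `sd` (sample SD, K − 1 denominator — the denominator is a
package choice and is recorded here), and `gini` (Gini mean difference).
The default is `re` with λ = ½, the equal-weighting case.

Forward selection starts from the base model (forced terms included from
cycle 0), scores every remaining candidate per cycle by a full IECV pass,
adds the argmin, and stops when the best candidate fails to improve the
previous cycle's loss (strict ≥ comparison, exactly as the stopping rule
is stated; an optional `min_improvement` epsilon defaults to 0), or when
candidates are exhausted. Ties break toward the earlier position in the
configured candidate ordering and are logged. Candidates whose IECV fails
in a cycle are skipped for that cycle with a warning, not dropped.
Backward selection mirrors this from the full model; forced terms are
never removal candidates. With `require_main_effects` on, an interaction
is eligible only once all its constituent main effects are in the model,
and selecting it locks those main effects in; the option is off by default
because published applications of this framework have admitted
interactions without their main effects. During selection only the MSE is
computed (cost); the final model's IECV reports all four metrics.

The loop is entirely deterministic — no randomness anywhere — so identical
data and configuration give byte-identical traces; serialization sorts
keys and uses repr floats to keep that true at the file level.

The global model pools all K cluster fits (no hold-out), then multiplies
slopes by the final cycle's summary calibration slope and adds the summary
calibration-in-the-large to the intercept. This linear shrinkage accounts
for the optimism of selection only approximately; wrapping the entire
SIECV in a bootstrap would be the thorough treatment and is deliberately
not implemented.

## Data handling choices

* Cluster order is first appearance in the input file; every loop uses it.
* No missing values are accepted; imputation belongs upstream.
* Scaling constants (age/25 and the like) live in the term definition, not
  in the data, so coefficients report on the transformed scale.
* Square terms are computed after within-cluster centering whenever
  requested, and by default a hold-out cluster is centered with **its own
  means** — a deployed model cannot know development-cluster means for a
  new setting. Centering from the development grand mean is available
  (`centering="development"`) because the alternative is defensible and
  the published examples do not say which was used.

## Synthetic data generator

`siecv.synthetic` draws exactly the model class above: α_k ~ N(μ_α, σ_α²),
β_{p,k} ~ N(μ_β, τ_p²), binary covariates with logit-normal cluster
prevalences, continuous covariates with normal cluster mean shifts, and
Bernoulli outcomes. The truth record stores every draw for recovery tests.
`dvt_like_preset()` mimics the *shape* of an 11-study deep-vein-thrombosis
diagnostic IPD set — 11 studies of uneven size totalling ~9 000–10 000
participants, overall event rate ≈ 0.19, three binary predictors with
pooled effects near (0.98, 1.27, 0.55) and moderate between-study SDs —
"inspired by" that setting, not a reproduction of any restricted dataset.

What the generator does *not* emulate: missing data and imputation
history, covariate correlation structures, measurement heterogeneity of
predictors (e.g. assay differences), non-logistic true risk, or informative
cluster sizes. Tests passing on this generator therefore show the
machinery is correct under the assumed model class, not that any specific
clinical model will transport.

## Test problem sizes and numerical conditions

Simulation-backed tests use deliberately modest problem sizes — e.g.
selection-recovery at K = 8–10 clusters of 150–200 participants over 100
replicates, τ² recovery at Q = 30 over 500 replicates, interval coverage
at Q = 15 over 2 000 replicates — chosen as the smallest scales at which
the checked properties are expected to hold cleanly. The
prediction-interval coverage check places per-cluster SEs (≈ 0.1–0.3)
well below the between-cluster SD (τ² = 0.2): the t_{Q−2} interval is an
approximation whose coverage is known to drift below nominal when
within-cluster error dominates, which is a property of the published
formula rather than of this implementation.

## Known limitations

* No multiple imputation, no survival or continuous outcomes, no
  categorical predictors beyond pre-encoded binaries.
* No bootstrap around the selection procedure; the calibration-based
  shrinkage is a first-order correction only.
* τ² is poorly estimable with few clusters (< 10) however estimated; the
  engine refuses to run with fewer than 3 development-viable clusters, but
  results with 3–9 clusters should be read with that caveat.
* λ must be prespecified; tuning it by nested resampling is out of scope.
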