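# Methods

## Data-generating process

Event and censoring times are drawn from log-linear accelerated-failure-time
(AFT) processes

    log T_i = μ + γ'Z_i + σ W_i,

where `W_i` has the standard minimum extreme-value density
`f(w) = exp(w − exp(w))`, sampled by inverse CDF (`W = log(−log U)`) for
platform-independent reproducibility.  With this residual law `T` is Weibull
with shape `α = 1/σ`; the model is equivalently a Weibull proportional-hazards
(PH) model with coefficients `β = −γ/σ`, which is what the Cox-type
estimators target.  Truth is always evaluated through the closed-form
conditional survival `S(t|z) = exp(−exp((log t − μ − γ'z)/σ))`.

Predictors: `p = 10` informative covariates from a zero-mean multivariate
normal with unit variances and common pairwise covariance 0.5
(compound symmetry), optionally padded with `q = 50` independent
standard-normal noise covariates that drive neither process.  Noise columns
are sampled independently of the informative block — the simplest reading of
"non-informative".

Defaults (the study conditions): `γ = (−0.5, −0.4, −0.3, −0.2, −0.1, 0.1,
0.2, 0.3, 0.4, 0.5)`, `μ_T = 0`, `σ_T = 0.58`.  The signal variance is
`γ'Σγ = 0.55`, so the coefficient of determination

    R² = var(γ'Z) / var(log T) = 0.55 / (0.55 + 0.58²·π²/6) ≈ 0.4985 ≈ 0.5.

The numerator is read as `var(γ'Z)` rather than `var(β'Z)`: with `β = −γ/σ`
the latter exceeds the total variance under these constants, so only the
γ-reading is consistent with an R² of one half.

Censoring: either **marginal** exponential (represented internally as an AFT
process with `σ = 1`, empty `γ` and `μ = −log λ_C`, so one sampler serves both
families) with rates `λ_C ∈ {0.219, 0.864, 3.013}`, or a **full**
covariate-dependent Weibull process with `σ_C = 0.58`, the same `γ`, and
intercepts `μ_C ∈ {0.800, −0.002, −0.803}`.  These pair with censoring levels
20 / 50 / 80 % by monotonicity — a larger rate (or smaller intercept) censors
more — and `calibrate_censoring` verifies the pairing by root search: given a
calibration sample of event times, the censoring fraction
`P(C < T | T, Z)` has a closed form in the parameter, is monotone, and is
solved by Brent's method on a default calibration sample of 10⁶.

Ties between `T` and `C` (a probability-zero event) count as events.  Each
cohort derives sub-streams for predictors, event residuals and censoring
residuals deterministically from one seed via `numpy` `SeedSequence` spawning.

## Estimators

All fitted models emit right-continuous step functions; per-individual curves
are sampled onto a shared equidistant grid.  The product-limit
(Kaplan-Meier) estimator is implemented in-house so that left limits and tie
handling are under control; it is cross-checked against lifelines in the test
suite.  Tie convention: risk sets at a jump include every observation with
time ≥ the jump, i.e. for the event-KM events precede censorings at a tied
timestamp, and symmetrically for the reverse KM (status reversed, censoring
is the event) censorings precede events.

Covariate-dependent adapters: Cox PH (lifelines), lasso-penalized Cox
(scikit-survival Coxnet), random survival forests (scikit-survival) and
boosted Cox (xgboost, `survival:cox`).  The PH-type adapters share an
in-house Breslow cumulative baseline hazard computed from the fitted linear
predictors, giving `S(t|z) = exp(−H₀(t)·e^{lp})` on the fitting data's event
times; this makes left-limit evaluation exact (the preceding step value,
never epsilon subtraction on floats).  Forest curves are evaluated on the
forest's own event-time grid.

Post-fit repairs: predicted curves are clipped to [0, 1] and made
non-increasing by a running minimum along the grid (forests and boosting can
emit locally non-monotone curves); beyond the last jump curves extend as
constants.  A censoring fit with zero censoring events (possible in tiny
splits) falls back to `G ≡ 1` with a warning rather than failing the
replicate.

Tuning is a pluggable contract: random search over each adapter's declared
hyperparameter space, scored by cross-validated concordance (3-fold default).
The first candidate is always the adapter's default configuration, so the
selected criterion never exceeds the untuned one and a budget of 1 returns
the defaults.  Cox and Kaplan-Meier have no space and pass through untouched.

## Scoring

IPC weights follow the standard two-term form with left limits `G(T*⁻)` for
past events.  A division by `Ĝ = 0` yields +∞ and is then capped; the cap
(default 5) is applied to the weights themselves *before* normalization, so
the effective sample size `ñ(t)` sums capped weights.  Grid points with
`ñ(t) = 0` are recorded as undefined (NaN), excluded from WSE sums, and
counted in a diagnostics field.

The expected uncensored Brier score of a fitted model is computed numerically
on a fresh uncensored reference population from the true process (default
10⁴ per replicate at desk scale; the original design used 10⁶ — the
reference's Monte-Carlo error only needs to be small relative to RWSE
differences, which holds at 10⁴ for the scenario grid used here).  The same
population supplies the event-density weights (normalized mean survival
decrements, with `t₀ = 0` so mass before the first grid point is captured)
and the grid itself: `k` equidistant points from just above 0 to the 99.9th
percentile of the reference event times.  `k` defaults to 10³ in the runner
(10⁴ in the original design; both configurable) — the density weighting makes
the RWSE insensitive to tail and refinement choices, which is covered by a
grid-refinement invariance test.

## Scenario runner

Each replicate: generate a cohort of `n_train + n_test`, split uniformly at
random (no stratification), fit the survival model on the training half,
predict on the test half, fit the censoring model separately on the training,
test and combined data, and score each option's IPCW Brier curve against the
expected reference by RWSE (reported on the natural-log scale for
aggregation).  Replicate seeds are derived by `SeedSequence` spawn-key
addressing, so results are independent of the execution order and of the
parallelization degree (joblib optional).  Failed replicates are logged and
skipped; a run aborts if more than 10 % fail.  Tunable censoring adapters are
re-tuned on whichever dataset they are fit to (a configurable choice; the
alternative of reusing training-fit hyperparameters is not implemented).

Named scenarios: `baseline` (marginal censoring, Cox/KM), `weibull_cox`
(full censoring, Cox/Cox), `misspecified` (full censoring, Cox/KM),
`low_noise` and `high_noise` (full censoring; Cox, lasso-Cox, forest and
boosted Cox each fit both processes; `q = 0` or `q = 50`).

## What the generator does and does not emulate

The synthetic cohorts realize proportional hazards exactly, have conditionally
independent event and censoring processes, time-constant covariates and a
single event type.  Real registry data violate most of these: censoring may
depend on unmeasured factors, hazards may cross, and covariates drift over
time.  Passing tests therefore demonstrate correctness of the weighting and
scoring machinery and the behavior of censoring-fit choices *under a
correctly specified world* (plus the one deliberate misspecification
scenario); they do not certify any particular censoring-fit choice for data
with informative censoring.

## Numerical choices and limitations

- Weight cap 5; capped-before-normalization (recorded in output metadata).
- Curves are step functions; all evaluations are index lookups, avoiding
  interpolation and float-epsilon tricks.
- Test-scale study sizes: scenario checks use 100 replicates (50 per design
  axis point) with a 500-point grid and a 10⁴ reference; these reproduce the
  qualitative orderings stably while keeping runs short.
- The Breslow baseline `exp(−H₀)` and the product-limit estimator differ at
  small risk sets (second-order in the hazard increments); tests compare them
  only where risk sets are large.
- Left truncation, competing risks, interval censoring and time-varying
  covariates are out of scope.
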