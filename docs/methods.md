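# Methods

## Model and decision rule

All analyses concern a generalized linear outcome model — logistic for a
binary outcome, log-linear Poisson for counts — with a single-term exposure
X, forced covariates W₁…W_J present in every model, and candidate covariate
groups U₁…U_H whose inclusion is decided from the data.  The exposure
effect is always read on the log odds/rate-ratio scale; ratios are
exponentiated only for display.

The selection currency is the estimated mean squared error of the exposure
coefficient.  For a reduced model evaluated against a referent model that
contains the deleted terms,

    ΔB      = β̂_reduced − β̂_referent
    Δ(SE²)  = SE²_referent − SE²_reduced
    ΔMSE    = (ΔB)² − Δ(SE²)
    RMSE    = sqrt((ΔB)² + SE²_reduced).

ΔMSE < 0 means the deletion trades a small squared-bias increase for a
larger variance decrease.  When Δ(SE²) > 0 the decision is equivalent to a
one-df collapsibility test χ²_c = (ΔB)²/Δ(SE²): retain iff χ²_c > 1,
i.e. iff the collapsibility P-value < 0.32.  This equivalence is asserted
property-wise in the test suite for every evaluated selection step.

Assumptions worth stating explicitly:

* the referent (full) model estimate is approximately unbiased — this is a
  working assumption, valid only when the measured covariate set and sample
  size are adequate;
* the exposure is one model term, so ΔB is scalar and χ²_c has 1 df
  (multi-term exposures are rejected at validation);
* the outcome is rare enough (or the model Poisson) that noncollapsibility
  of the odds ratio is negligible; for common outcomes the χ²_c test
  conflates noncollapsibility with confounding and a collapsible effect
  measure should be used instead — out of scope here;
* SEs after selection do not account for the selection itself; the
  selection-aware bootstrap exists precisely because of this.

### Degenerate and boundary cases

* Δ(SE²) ≤ 0 with ΔB ≠ 0: the deletion failed to reduce variance, ΔMSE ≥ 0
  necessarily, the candidate is retained; χ² and P are reported as
  undefined rather than infinite.
* ΔB = 0 and Δ(SE²) = 0 (e.g. a self-comparison): χ² = 0, P = 1.
* A worked-value caveat: for the regime with coefficients ln 3 vs ln 2 and
  SEs 0.14 vs 0.24, the collapsibility statistic is
  (ln 1.5)²/(0.24² − 0.14²) = 4.33; a commonly quoted value of 4.03 for
  this configuration does not reproduce from its own inputs and is not used
  as a test anchor.

## Fitting

One weighted Newton–Raphson solver (step-halving on the objective,
gradient max-norm < 1e-8 or 50 iterations) backs three fit routes:

* **ML** — logistic or Poisson.  A logistic fit whose coefficients pass
  |β| > 15 mid-iteration is flagged as separated (odds ratios beyond e¹⁵
  carry no information at these sample sizes), warned about, and returned
  with `converged=False`; non-convergence is a flag, never an exception.
* **Firth** — Jeffreys-prior penalized likelihood, penalty ½·ln det I(β),
  implemented via the hat-diagonal score correction; finite estimates exist
  under complete separation, and the full-model Firth fit is the default
  bias standard for comparison reports.  Logistic only.
* **log-F(m,m)** — shrinkage priors imposed by data augmentation: for each
  penalized coefficient, two pseudo-records (one success, one failure) with
  the term set to 1/unit_scale and all else zero, each with weight m/2
  (½ for F(1,1), 1 for F(2,2)); the intercept column is replaced by an
  actual-data indicator so pseudo-records inform only the penalized terms;
  the augmented data are then fit by ML.  The F(1,1) prior puts 95%
  probability on the odds ratio in (1/648, 648), F(2,2) in (1/39, 39).
  By default all non-intercept terms are penalized, configurable via
  `PriorSpec.penalized_terms` — penalizing or sparing the forced terms is
  a modelling choice the interface leaves open.

The solver is authored in-package (rather than delegated to a library GLM)
so that the three routes share one controlled code path and so that the
selection-aware bootstrap, which refits models hundreds of thousands of
times, stays fast; library fits serve as independent oracles in the tests.
Covariance is the inverse (penalized) Fisher information at the optimum.
AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln n always use the actual-record count
for n, never pseudo-records.

## Selection engines

All engines move candidate groups atomically (a categorical covariate's
dummies enter and leave together), never touch the exposure or forced
terms, break ties by spec order (determinism), and log every evaluation.

* **mse_backward** — from the full model, drop the candidate with the most
  negative ΔMSE; repeat until none is negative.  Aborts with advice
  (forward selection or penalization) if the full model does not converge.
* **mse_forward** — from the minimal model, add the candidate whose absence
  costs the most MSE (largest positive ΔMSE of the current model against
  the expanded referent); repeat.  One signed quantity
  D = (β̂_without − β̂_referent)² − (SE²_referent − SE²_without) drives both
  engines: backward drops on D < 0, forward adds on D > 0.
* **referent mode** — `larger_model` (default): the referent is the larger
  of the two models in each comparison; `full_model`: the initial full fit
  is the referent for every step.
* **stepwise_p** — joint Wald chi-squared of each group's terms; presets
  α = 0.20 and 0.05, forward and backward.
* **stepwise_aic / stepwise_bic** — greedy best-improvement search.
* **cie** — change-in-estimate on the ratio scale,
  |exp(β̂_new − β̂_old) − 1| against a threshold (default 10%).

Candidate refits that fail or do not converge are recorded as `skipped`
and the candidate retained — a failed fit is never treated as ΔMSE
evidence.  Effect-measure-modification checks (exposure-by-covariate
product terms) are exposed as a post-hoc report
(`heterogeneity_report`), never as a selection criterion.

Exhaustive subset search (`exhaustive_best_roster`) is provided as a
small-H oracle only.  Greedy one-at-a-time selection need not reach the
subset with the overall smallest estimated MSE; the test suite carries a
fixture exhibiting a strict gap of ≈0.07 RMSE.

## Selection-aware bootstrap

Records are resampled with replacement, unstratified, and the entire
procedure — selection included — is rerun per resample; resamples that
select a different roster are kept, since that variability is the point.
Per-resample RNG streams are keyed by (seed, resample index), making
results independent of execution order.  Intervals are percentile or BCa;
the BCa bias-correction constant comes from the proportion of resample
estimates below the point estimate and the acceleration from leave-one-out
jackknife influence values of the same procedure.  Resample failures are
counted; >10% attaches a warning, total failure raises.  The conventional
resample count for reporting is 4000 (the package default); tests use
100–600.

## Synthetic scenarios

The generator draws covariates (Bernoulli or standard normal, the normal
block optionally equicorrelated at `collinearity_r`), links a binary
exposure to them through a logistic model whose intercept is calibrated by
root-finding to the requested prevalence, or — for a continuous exposure —
embeds the exposure in the joint normal block with
`association_with_exposure` read as a correlation; the binary outcome then
follows a logistic model with the stated coefficients and a baseline risk
of 0.05 by default (rare-outcome regime, OR ≈ RR).

Preset regimes and their signatures (asserted statistically in tests):

| preset | structure | signature |
|---|---|---|
| `null` | two noise candidates | engines mostly return the minimal model |
| `confounder` | binary U: OR 3 on outcome, OR 3 on exposure | crude−adjusted shift ≫ replicate noise, modest SE change |
| `collinear_nonconfounder` | normal U: β=0 on outcome, 2.0 on exposure logit | SE inflation >10% with essentially unchanged coefficient |
| `collinear_confounder` | as above with β=0.7 on outcome | bias–variance trade-off regime |
| `sodium_potassium_like` | continuous exposure, r = 0.81 with a continuous candidate | correlated-pair regime |
| `atopy_like` | one dominant confounder among weak candidates, forced covariate, baseline risk 0.15 | all strategies converge on the dominant confounder |

What the generator does **not** emulate: measurement error, missing data,
survival time, clustered sampling, and effect-measure modification.
Passing tests therefore demonstrate the machinery's behaviour under clean
logistic data-generating processes with known truth, not robustness to
those real-data features.

A quantitative note on the `collinear_nonconfounder` regime: whenever the
deleted covariate is truly ignorable, the drop decision is asymptotically
the event {χ²₁ < 1}, whose probability is 0.683 — no deletion rule based
on this statistic drops an ignorable collinear covariate much more often
than that, and the replicate tests assert a band around this value rather
than a higher rate.  Symmetrically, forward stepwise at α = 0.20 admits a
pure-noise candidate with probability ≈0.2 by construction.

## Problem sizes used in the test suite

Deterministic arithmetic checks run on printed summaries (no data).
Simulation-backed tests use n = 150–5000 per dataset with 20–200
replicates, parameter recovery uses single datasets of n = 20 000, and
the bootstrap coverage check uses 200 replicates × 500 resamples at
n = 250 — sizes at which every asserted property is comfortably resolved
by the stated tolerances.  The dominant-confounder consensus check uses
n = 3000, where all six strategies agree within 1% on the ratio scale.

## Known limitations

* Cox/time-to-event regression is not implemented; Firth and log-F fits
  are logistic-only.
* Multi-term exposures (splines, multiple dummies) are rejected; the
  collapsibility statistic implemented is the single-coefficient version.
* Post-selection model-based SEs are anti-conservative; use the bootstrap.
* The χ²_c criterion presupposes a variance decrease from deletion; when
  Δ(SE²) ≤ 0 the package retains the candidate rather than testing.
* For common outcomes the odds ratio is noncollapsible and the criterion
  mixes noncollapsibility with confounding; switch to collapsible measures
  (risk ratio/difference via standardization) in that regime.
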