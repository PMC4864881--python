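# mse-select

Confounder selection for epidemiological outcome regression by estimated
mean squared error, with penalized fits and a selection-aware bootstrap.

## The problem

When estimating the effect of an exposure X on a binary outcome Y with a
logistic (or Poisson) regression, the analyst must decide which measured
covariates to adjust for.  Dropping a confounder biases the exposure
coefficient; retaining a covariate that is strongly associated with the
exposure (multicollinearity) inflates its standard error.  Conventional
selection tools — stepwise testing of covariate coefficients, AIC/BIC,
change-in-estimate rules — optimize prediction or test the wrong
hypothesis.  `mse-select` targets the quantity an epidemiologist actually
cares about: the accuracy of the exposure effect estimate.

## The criterion

Write β̂ for the exposure coefficient (log odds or rate ratio).  Taking a
referent model's estimate as approximately unbiased, the accuracy of a
reduced model is its estimated mean squared error, MSE = B² + SE², where
B = β̂_reduced − β̂_referent.  Deleting a candidate covariate changes the
estimated MSE by

    ΔMSE = (ΔB)² − Δ(SE²),
    ΔB = β̂_reduced − β̂_referent,   Δ(SE²) = SE²_referent − SE²_reduced.

Deletion is harmless when ΔMSE < 0 (the variance saved exceeds the squared
bias introduced).  When Δ(SE²) > 0 the same decision can be read as a
one-degree-of-freedom *collapsibility test*

    χ²_c = (ΔB)² / Δ(SE²),

with ΔMSE > 0 ⇔ χ²_c > 1, i.e. a candidate is retained exactly when the
collapsibility P-value is below 0.32.  Backward deletion drops the
candidate with the most negative ΔMSE until none remains; forward
expansion mirrors it.  Models are compared by the root of the estimated
MSE (RMSE = √(B² + SE²)) against a bias standard — by default the Firth
bias-reduced full-model fit.

Also provided: log-F(m,m) shrinkage priors imposed by data augmentation
(two weighted pseudo-observations per coefficient), a sparse-data
diagnostic (≈4 subjects per confounder coefficient in each exposure-outcome
cell), the usual comparator strategies, and bootstrap percentile/BCa
intervals that rerun the entire selection on every resample.

## Worked example

Simulate a survey-like dataset with one dominant confounder (`town`),
a forced covariate (`sex`) and two weak candidates, then compare
strategies:

```sh
mse-select simulate --preset atopy_like --n 3000 --seed 5 --out atopy.csv
cat > cfg.yaml <<'EOF'
outcome: y
exposure: x
forced: [sex]
candidates: [town, firstborn, smoker]
strategies: [mse-backward, mse-forward, cie, stepwise-aic]
EOF
mse-select compare --data atopy.csv --config cfg.yaml --out-prefix atopy_report
```

`atopy_report.tsv` (abridged columns):

```
model         roster                  coefficient  se     ratio  bias   rmse   chi2   p_value
basic         (minimal)               0.693        0.080  2.00   0.356  0.365  114.23 0.0000
ml-full       firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087
firth-full    firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087  0.00   1.0000
mse_backward  firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087
mse_forward   firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087
cie           town                    0.344        0.087  1.41   0.007  0.087  3.75   0.0527
stepwise_aic  firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087
logF-1-1      firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087  0.02   0.8841
logF-2-2      firstborn+smoker+town   0.337        0.087  1.40   0.000  0.087  0.01   0.9308
```

Reading the table: the unadjusted ("basic") model overstates the exposure
odds ratio (2.00 vs ≈1.40) because `town` confounds the association — its
estimated bias 0.356 dominates the RMSE 0.365.  Every selection strategy
keeps `town` and lands within a few percent of the full model; the
collapsibility χ² of 114 on the basic row says the minimal model is far
from collapsible over the candidates.  `atopy_report.json` carries the
same rows at full precision plus the complete selection trace (every ΔMSE
or criterion value evaluated at every step).

The same analyses are available as library calls
(`mse_select.select_backward_mse`, `mse_select.run_strategy`,
`mse_select.bootstrap_procedure`, ...), which is the more convenient
surface for simulation studies.

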