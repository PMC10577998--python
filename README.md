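# tmlecat

Targeted maximum likelihood estimation (TMLE) of the association between an
ordinal country-level exposure and a log-transformed burden-of-disease
outcome, with a cross-validated stacking ensemble ("SuperLearner") for
nuisance estimation.

The package is built for ecological analyses of the kind used to study how
globalization relates to the burden of opioid use disorders: one row per
country, a 1–100 globalization index discretized into four levels
(Low [41, 64], Mid-Low (64, 72], Mid-High (72, 82.5], High (82.5, 91]),
age-standardized DALYs per 100,000 as the outcome (analyzed on the natural
log scale so mean log differences read approximately as percent
differences), and a covariate set of country-level confounders
(Socio-Demographic Index, unemployment, income inequality, urbanization),
a pre-exposure baseline burden, and precision covariates (child sexual
abuse SEV, data-quality stars, healthcare access & quality). It is aimed
at epidemiologists and biostatisticians who want the full pipeline —
ingest, discretization, nuisance estimation, targeting, contrasts,
positivity diagnostics, sensitivity grid — as tested, reusable code, plus
a synthetic country-panel generator with known causal truth for
validating the machinery.

## The estimator

For exposure level `a ∈ {0,1,2,3}`, covariates `W` and log outcome `Y`,
the estimand is the counterfactual mean `ψ_k = E[Y(k)]` at each level and
the contrasts `β_k = ψ_k − ψ_0` against the Low reference. Estimation:

1. **Outcome regression** `Q(a, W) = E[Y | A=a, W]`, fit by a stacking
   ensemble over five base learners (main-effects linear model,
   forward-stepwise regression by AIC, L1-regularized linear model, MARS
   with interaction degree 2, random forest with 500 trees / 2 variables
   per split / minimum node size 5), with simplex weights chosen to
   minimize 10-fold cross-validated squared error.
2. **Exposure mechanism** `g_k(W) = P(A=k | W)`, the same ensemble in
   multinomial mode (minimum node size 1 for the forest; weights minimize
   cross-validated multinomial log-loss).
3. **Stabilized, trimmed weights** `s_ik = 1(A_i=k) · p̂_k / g_k(W_i)`,
   capped at the 99.9th percentile of the positive ratios (99 and 97.5
   as sensitivity variants).
4. **Targeting**: the outcome is min–max scaled to [0, 1]; a weighted
   intercept-only logistic fluctuation per level updates `Q` so the
   efficient-influence-function score equation is solved; `ψ_k` is the
   mean updated counterfactual prediction.
5. **Inference**: influence-curve standard errors; contrast SEs from
   `SD(IC_k − IC_0)/√n`; Wald 95% CIs and normal p-values. Because the
   marginal structural model with one dummy per non-reference level is
   saturated, OLS of the targeted predictions on the dummies reproduces
   the contrasts exactly — the package computes both routes and checks
   they agree.

The estimator is doubly robust: consistent if either the outcome
regression or the exposure mechanism is estimated consistently.
Positivity is verified descriptively from the weight distribution (a
maximum weight of 50.1 means every country kept at least a 1/50.1 ≈ 2%
probability of its exposure level).

## Worked example

```python
from tmlecat import (SimConfig, generate_panel, estimate_outcome_regression,
                     estimate_propensities, CategoricalTMLE,
                     contrasts_vs_reference, weight_summary,
                     positivity_report, cv_performance)

panel, truth = generate_panel(
    SimConfig.for_scenario("baseline", n_countries=500, seed=7))
cfg = {"folds": 10, "seed": 7,
       "learners": ["linear_main_effects", "stepwise_forward",
                    "l1_linear", "mars"]}
Q, qm = estimate_outcome_regression(panel, cfg)
g, gm = estimate_propensities(panel, cfg)
tmle = CategoricalTMLE(trim_percentile=99.9).fit(
    panel.outcome_log, panel.levels, Q, g)
print(contrasts_vs_reference(tmle.estimates_).table.round(3))
print(positivity_report(weight_summary(tmle.nuisance_))[1])
```

Output:

```
                  beta     se  ci_low  ci_high    p percent_approx
contrast
High vs Low      0.371  0.033   0.306    0.436  0.0            37%
Mid-High vs Low  0.191  0.036   0.121    0.262  0.0            19%
Mid-Low vs Low   0.172  0.034   0.105    0.240  0.0            17%
Positivity verified: maximum weight 2.9 implies every country had a
probability of exposure of at least 34% (1/2.9); mean weight 0.9 implies
a mean probability of at least 100%.
```

The generating truth for this draw is `β = (0.13, 0.14, 0.31)` (Mid-Low,
Mid-High, High vs. Low): every 95% CI covers its true contrast, and the
`beta` column reads as a mean log difference — `0.371` ≈ a 37% higher
burden at the High level, with the exact factor `exp(β) − 1` reported
alongside in the `percent_exact` column.

The same machinery runs from the command line over the full sensitivity
grid (three trimming percentiles × outlier removal on/off):

```sh
tmlecat simulate --scenario baseline --seed 7 --n 87 --out panel.csv
tmlecat run --config study.yaml --out results/
```

which writes the master contrast table (CSV), weight diagnostics (JSON),
the run configuration, and a forest plot per outcome.

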