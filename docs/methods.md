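# Methods

## Estimand and model

The package estimates counterfactual mean log outcomes `ψ_k = E[Y(k)]`
for a four-level ordinal exposure and reports the saturated
marginal-structural-model contrasts `β_k = ψ_k − ψ_0` against the lowest
level. Identification assumes no unmeasured confounding given the
covariate set (four confounders, the pre-exposure log outcome, three
precision covariates), positivity, and the usual consistency/SUTVA
conditions. The design is cross-sectional with a pre-exposure baseline:
no temporal dependencies are modeled, and continuous-exposure (shift)
estimands are out of scope.

Outcomes are analyzed on the natural log scale. This makes a contrast
`β` readable as an approximate percent difference (`β = 0.31` ≈ 31%);
the exact factor `exp(β) − 1` is always reported alongside because the
approximation degrades beyond |β| ≈ 0.2.

## Targeted estimation

1. **Initial outcome regression.** One pooled ensemble regression of the
   log outcome on level dummies plus covariates; the counterfactual
   matrix `Q` (n×4) is the refit ensemble evaluated with the dummies
   forced to each level. No cross-fitting is applied (the target
   application has n ≈ 87; see Limitations).
2. **Exposure mechanism.** An ensemble multinomial classifier on the
   covariates; probabilities are floored at 1e-6 and rows renormalized.
3. **Stabilized weights.** `s_ik = 1(A_i = k) p̂_k / g_ik` with `p̂_k`
   the empirical level share. Trimming caps ratios at the chosen sample
   percentile (99.9 default; 99 and 97.5 as sensitivity variants) of the
   pooled positive ratios; per-level trimming is available via
   `stabilize_and_trim(..., pool="per_level")` since the pooling
   population is a genuinely open choice.
4. **Fluctuation.** The outcome and `Q` are min–max scaled to [0, 1]
   (with `Q` bounded into [0.005, 0.995] to keep logits finite — the
   standard device for bounded continuous outcomes). For each level an
   intercept-only logistic fluctuation `ε_k` solves the weighted score
   equation `Σ_{A_i=k} s̃_ik (y_i − expit(logit(Q_ik) + ε_k)) = 0`,
   found by bracketed root-finding (monotone score; xtol 1e-12).
   `ψ_k` is the mean of the unscaled updated predictions.
5. **Inference.** `IC_ik = (s̃_ik/p̂_k)(y_i − Q̃_ik) + Q̃_ik − ψ_k`;
   the trimmed stabilized ratio is de-stabilized inside the IC so that
   stabilization affects trimming but not the estimand. SEs are
   `SD(IC)/√n`; contrasts use `SD(IC_k − IC_0)/√n`; Wald CIs use normal
   quantiles (a t reference would change the 95% quantile by <2% at
   n = 87 and is not used). Solving the score equation makes each IC
   column mean-zero by construction, which the tests verify to 1e-6.

The saturated-MSM identity (OLS of stacked targeted predictions on level
dummies equals the subtraction contrasts) holds to numerical precision
and is recomputed in every pipeline cell as an internal consistency
check.

## The stacking ensemble

Five base learners with fixed hyperparameters: main-effects linear
model; forward-stepwise selection from the intercept by AIC; L1 linear
model with the penalty chosen by inner cross-validation; MARS with
maximum interaction degree 2; random forest with 500 trees, 2 candidate
variables per split, minimum node size 5 (regression) or 1
(classification). Out-of-fold predictions over a seeded 10-fold split
(stratified by level for the multinomial task; 5 folds are used in the
large simulation studies below) feed the meta-learner:

- regression: non-negative least squares followed by projected-gradient
  refinement on the probability simplex (the MSE objective is convex, so
  the returned weights are simplex-optimal, not merely normalized NNLS);
- multiclass: projected-gradient descent on the multinomial log-loss
  with backtracking, iteration cap 2000, tolerance 1e-8.

A learner that raises on any fold is dropped with a warning and the
weights renormalize over the survivors. Performance indicators are
cross-validated R² and macro one-vs-rest AUC, computed from out-of-fold
predictions only.

Multiclass adaptations: the linear and stepwise learners become
multinomial-logistic counterparts; the L1 learner is one-vs-rest L1
logistic regression (liblinear with an inner CV over the penalty) with
probabilities renormalized across classes — an order of magnitude faster
than multinomial-L1 solvers at the sizes used here, with
indistinguishable risk; MARS fits one regression per class indicator and
normalizes clipped scores. MARS itself is implemented in-package
(forward selection of mirrored hinge pairs with correlation screening,
backward pruning by GCV with penalty 3), since no maintained Python MARS
is available.

## Synthetic country panels

The generator emulates the target data: one row per country with SDI,
unemployment, income inequality (p90p100), urbanization, child-sexual-
abuse SEV, data-quality stars (3–5, SDI-dependent), healthcare access &
quality (strongly SDI-driven), and a 1990 baseline log burden. A latent
globalization score is a linear combination of SDI (+), inequality (−),
urbanization and HAQ plus Gaussian assignment noise; fixed thresholds at
the 23/87, 46/87, 65/87 quantiles of the population score (computed once
on a large internal fixed-seed draw) cut it into four levels with splits
resembling 23/23/19/22, and a monotone piecewise-linear map renders the
score as an index on the 41–91 scale consistent with the level bins.
Because the assignment noise is Gaussian, true propensities are analytic
normal-CDF differences — every panel ships with its exact `g` and `Q`
matrices and its true contrasts.

The log outcome is `intercept + θ_level + confounder effects + baseline
effect + N(0, σ)` with defaults `θ = (0.13, 0.14, 0.31)` (Mid-Low,
Mid-High, High vs. Low) — magnitudes chosen so desk runs resemble
published burden analyses; this is a simulation convention, not a
reproduction claim. Key scales, chosen once:

- **Outcome noise σ = 0.25** on the log scale. With the lagged 1990
  burden in the covariate set, little residual variation remains in real
  burden panels; this scale also makes a single n = 5000 fit a sharp
  test of estimator bias (contrast sampling SE ≈ 0.01).
- **Assignment noise 1.8** latent-scale units (latent R² ≈ 0.3, exposure
  AUC ≈ 0.6): strongly confounded but positivity-healthy. With tighter
  assignment the true weight distribution develops tails (ratios > 40)
  under which percentile trimming itself induces bias of order 0.05
  regardless of the estimator, so the generator deliberately stays clear
  of that regime.

Scenarios: `baseline`; `zero_effect` (θ = 0); `strong_confounding`
(outcome-side confounder effects ×2.2, assignment noise 2.6, unadjusted
contrasts biased by 0.2–0.5 log-units); `nonlinear_Q` (curvature and a
level-dependent effect modifier, so the truth comes from the Monte-Carlo
oracle `true_contrasts_oracle`); `misspecified_g` (curved latent score
that a multinomial logit cannot match). Under additive scenarios the
true contrasts equal θ exactly; the oracle reproduces them within
Monte-Carlo error.

What the generator does **not** emulate: GBD estimation uncertainty,
spatial correlation between countries, covariate dependence beyond the
SDI→HAQ/stars links, and measurement error in the exposure index.
Passing tests therefore validate the estimation machinery, not the
substantive findings of any real-data analysis.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run, with all randomness
seeded:

- parameter recovery: one full-library fit at n = 5000 (5 CV folds;
  errors observed ≤ 0.005 against truth, bound 0.02);
- CI coverage: 300 replicates at n = 500 with the linear + L1 library,
  High-vs-Low coverage in [0.93, 0.97];
- double robustness: 100 replicate draws of `strong_confounding` at
  n = 5000, analytic truth for the correct nuisance and deliberately
  wrong-covariate parametric fits for the misspecified one;
- efficiency: empirical SD of the targeted contrast vs. Hajek IPW over
  60 replicates;
- worked-number checks, the saturated-MSM identity, trimming
  monotonicity, and the no-confounding identity (with marginal
  propensities and a level-constant initial regression the targeted
  means equal per-level sample means exactly).

These sizes keep the whole suite under ten minutes on one CPU while
leaving Monte-Carlo error small against each bound.

## Numerical choices

- Quantiles/percentiles everywhere are linear-interpolation sample
  quantiles; outlier removal excludes outcomes strictly outside the
  [1st, 99th] percentile band.
- Exposure discretization takes the printed interval notation literally:
  first bin closed on both ends, others left-open; values outside
  [41, 91] are errors, never clamped; boundary ties go to the lower
  level.
- Missing data are rejected with an itemized per-country report; no
  imputation. The data-quality filter (≥3 stars) applies at ingest.
- Degenerate inputs raise informative errors: constant outcome, a level
  absent, rank-deficient dummy designs, propensity rows off the simplex.
- All-tied Kruskal-Wallis inputs return H = 0, p = 1 with a warning
  instead of failing.
- Stabilized ratios below 1 are legitimate; probability readings from
  weight reciprocals are capped at 100% in narratives and flagged with a
  warning in `implied_min_probability`.

## Known limitations

- **No cross-fitting.** Nuisance predictions come from ensembles refit
  on the full sample. With flexible learners (the random forest above
  all) this overfits at small n: in-sample residuals shrink, weights
  flatten, and IC-based SEs become optimistic. At n = 87 with the full
  library the reported SEs can understate the sampling SD severalfold;
  with the parsimonious linear + L1 library calibration is accurate from
  n ≈ 500 (coverage 0.95). This mirrors the analysis design the package
  implements; users wanting honest small-n inference should prefer the
  parsimonious library or interpret CIs cautiously.
- Mid-level contrasts show mild finite-sample undercoverage (≈ 0.92 at
  n = 500) relative to the High contrast (0.95); a joint test across all
  three contrasts is therefore slightly anti-conservative.
- Percentile trimming is a bias-variance trade-off: under weak overlap
  it stabilizes estimates but biases them when the outcome regression is
  misspecified. The sensitivity grid (99.9/99/97.5) exposes this rather
  than hiding it.
- The multiple outcomes of a multi-outcome run are reported without
  multiplicity correction, matching the reporting convention of the
  analyses this package mirrors; this is deliberate and documented, not
  an oversight.
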