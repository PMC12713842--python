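# Methods

## The model

`ordmediate` estimates serial multiple mediation models in which an
exposure X (here a gratitude sum score) acts on a 4-level ordinal outcome
Y (frequency of sleep disturbance, coded 0–3) through an ordered chain of
continuous mediators:

* **first-order mediators** M1 (health self-efficacy and/or health
  behaviors), regressed on X and covariates by OLS;
* **second-order parallel mediators** M2 (stress, anxiety, depression),
  regressed on X, the M1s and covariates by OLS — parallel means no paths
  among the M2s themselves;
* an **outcome equation**: a cumulative-odds ordinal logistic regression

      logit P(Y > j | x) = α_j + Σ_k β_k x_k ,   j = 0, 1, 2.

All predictors are standardized (z-scores, n−1 SD) before fitting, so a
slope is the effect of a one-SD difference and coefficients are
commensurable across the linear and logistic stages; the ordinal outcome
itself is never standardized. With this parameterisation a positive β
means higher odds of a *more frequent* outcome and the fitted α_j
decrease in j; `exp(β)` is reported as an odds ratio.

**Partial proportional odds.** The common-slope (proportional-odds)
constraint is tested per candidate predictor with a likelihood-ratio test
against a fit in which that predictor receives one slope per cut
(df = 2 per relaxed predictor for a 4-level outcome). When more than one
candidate violates the constraint, the all-relaxed model is compared to
each singly-relaxed model; if it does not beat all of them, the
singly-relaxed model with the higher log-likelihood is kept (ties: fewer
parameters, then name order). No ordering constraint is placed on per-cut
slopes; steps that would drive a fitted cell probability
P(Y = j) = P(Y > j−1) − P(Y > j) non-positive are rejected by the line
search.

**Indirect effects.** Because all stages use standardized coefficients,
every mediation pathway's effect is the product of the coefficients along
it (product-of-coefficients method), spanning OLS and ordinal-logit
stages. A mediator with per-cut slopes contributes one specific pathway
per cut (labels `a1*b1`, `a1*b2`, `a1*b3`); serial pathways
X → M1 → M2 → Y use the single OLS d-coefficient and M2's outcome slope.
By construction the total effect decomposes exactly:
c = c′ + Σ(indirect). Opposite-signed direct and total-indirect estimates
raise a suppression flag.

## Estimation and numerics

* **OLS stages** are exact least squares with classical covariance SEs,
  t-based p-values and 95% CIs (delegated to statsmodels).
* **The cumulative/partial-PO likelihood** is maximised by Newton
  iterations with analytic gradient and Hessian and step halving; a
  quasi-Newton (L-BFGS-B) fallback handles the rare stalled step.
  Starting values are the empirical cumulative logits for the α_j and
  zeros for slopes; convergence requires gradient max-norm < 1e-6
  (iteration cap 500). Step acceptance tolerates objective changes below
  1e-13·|ℓ| so ulp-level noise near the optimum cannot stall the line
  search. SEs come from the observed information (analytic Hessian) at
  the optimum; coefficient tests are Wald z.
* **Model-family comparison.** The cumulative model is compared to a
  baseline-category multinomial logit by an LRT on the log-likelihood
  difference with df = parameter difference. The two families are not
  strictly nested; the comparison replicates common applied practice and
  the caveat is recorded in the selection trace.
* **Degenerate inputs.** Rank-deficient designs raise an error naming the
  collinear column set; outcomes with fewer than two observed categories,
  zero-variance columns in standardization, and p-values outside [0, 1]
  are rejected up front. Correlation cells with fewer than 3 complete
  pairs are reported missing, never zero.

## Inference

* **Percentile bootstrap.** B case resamples (default 10,000 in the CLI;
  tests and the acceptance script use 200–1,000) are drawn with
  replacement from the complete cases of the most inclusive equation.
  Within each resample the predictors are re-standardized, every equation
  is refit (ordinal refits warm-start at the full-sample solution, point
  estimates only), and each pathway product is stored. Model structure —
  the non-parallel set and the retained covariates — is frozen before
  resampling; selection is not re-run inside the bootstrap. CIs are
  type-1 (inverse empirical CDF) quantiles of the draws, so intervals are
  bit-reproducible from serialized draws; the bootstrap SE is the draw SD.
  Replicate b uses the `(seed, b)` substream of a counter-based seed
  sequence, so enlarging B never reshuffles earlier replicates. Failed
  replicates (lost outcome category, degenerate resample, non-converged
  refit) are dropped; more than 1% triggers a warning and more than 10%
  an error.
* **Multiplicity.** Coefficient p-values are BH-FDR adjusted, pooled per
  model over all of that model's equations including intercepts and
  thresholds (a switch allows pooling across models). Elimination
  decisions use raw p-values; adjusted values are reported afterward.
* **FCR-corrected intervals.** With n_selected of n_total effect CIs
  excluding zero at the nominal level, selected-parameter intervals are
  re-reported at level 1 − q·(n_selected/n_total) (the false coverage
  rate construction) — e.g. q = 0.05 and a 60% selection fraction give
  0.97. The level can also be fixed by the caller (`fcr_level=0.97`)
  to replicate a published analysis exactly. "Significant" means the
  FCR-corrected CI excludes zero.

## Model-building decisions

Backward covariate elimination removes, per equation, the covariate with
the largest p-value above α = 0.05 (t for OLS, Wald z for the ordinal
equation), refitting after each removal; the exposure and mediators are
never eliminable. A nominally non-significant covariate is retained when
its removal significantly worsens overall fit by a likelihood-ratio test
at α (default). An AIC-based guard (`criterion="aic"`) is available, but
it is not the default because an AIC guard retains a pure-noise covariate
whenever its |t| exceeds √2 — about 16% of the time — which we judged too
permissive for a procedure whose goal is to discard uninformative
covariates; the LRT guard is coherent with the p-value rule and removes
pure noise at the expected ~95% rate while retaining a 0.3-SD effect at
n = 1,000 essentially always. Within one equation's elimination loop the
complete-case row set is frozen at the full starting variable set so all
AIC/LRT comparisons share one sample; the final model is refit on the
final variable set's complete cases.

Missing data are handled by complete-case analysis per fitted equation
(each equation drops rows incomplete for its own variables); correlations
use pairwise-complete observations. No imputation is attempted.

## The synthetic-data generator

The generator emulates the respondent-level structure the analysis
assumes, with known truth for recovery testing. Structural equations are
specified on standardized scales: continuous mediators are linear
combinations of their standardized parents plus Gaussian noise; the
outcome arises from a latent-logistic cumulative process,
P(Y > j) = logistic(α_j + x'β) with α_j = −threshold_j, with optional
per-cut slope offsets to create proportional-odds violations. Residual
SDs default to `auto` = √(1 − Var(systematic)), floored at 0.05, so every
structural variable has approximately unit variance and configured path
coefficients are directly comparable to standardized fit estimates.

Defaults emulate a German primary-care survey sample: gratitude
~ N(33.44, 6.53²); age ~ N(53.00, 11.96²) truncated to [20, 92]; sex
~ Bernoulli(0.607) (1 = female); education an ordinal 1–5 with
frequencies (0.056, 0.228, 0.334, 0.294, 0.088); chronic conditions
~ Poisson(1.79) truncated at 8; outcome thresholds set to the empirical
cumulative logits of category frequencies (24.6, 45.9, 15.2, 14.3)%;
path coefficients mirror the first worked-example model, including
per-cut self-efficacy offsets (+0.124, −0.141, +0.018) around a base
slope of −0.224. Mediator columns are back-transformed to survey-scale
marginals for output; missingness is MCAR at a configurable cell rate
(< 0.2).

What the generator does **not** emulate: the motivating data are
observational, so all generative choices here are stand-ins (and are
labelled as such in the truth sidecar). Real survey scores are bounded
and discrete, mediators here are continuous and unbounded after
back-transformation; covariates are drawn independently rather than with
the empirical covariate intercorrelations; age truncation and the
Poisson cap perturb the theoretical standardizing moments by under 1%.
Passing recovery tests therefore show the estimation machinery is
correct under the assumed structural model, not that the model is
correct for any particular data set.

## Problem sizes used in tests and the acceptance script

Exact checks (worked-example arithmetic, closed-form intercepts,
pseudo-inverse and brute-force BH oracles) run in well under a second.
Simulation checks use sizes chosen to give tight Monte-Carlo error at
single-CPU scale: proportional-odds LRT size over 500 replicates and
power over 100 replicates at n = 2,000; bootstrap coverage over 100
seeds at n = 2,000 with B = 500; the null false-positive rate of the
serial-path CI over 200 replicates at n = 500 with B = 1,000. The
acceptance script repeats the calibration and coverage summaries at
reduced scale (200/60 replicates, 30 coverage seeds) so a full run
completes in about a minute and a half.

## Known limitations

* Only the logit link is provided (no probit or cloglog), matching the
  cumulative-odds formulation; no robust/sandwich SEs or random effects.
* Percentile intervals only — no BCa; percentile bootstrap is known to be
  near-nominal but slightly liberal for products of coefficients at
  small n.
* The cumulative-vs-multinomial LRT is a conventional but non-nested
  comparison; interpret its p-value descriptively.
* Education is treated as a numeric ordinal score, and sex as a 0/1
  indicator (1 = female), in both generator and examples.
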