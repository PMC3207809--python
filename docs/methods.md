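# Methods

## Scope and data model

The package estimates sparse prognostic signatures from four linked
genomic platforms (mRNA expression, DNA methylation beta values,
copy-number values, microRNA expression) against right-censored
follow-up recorded in months. All estimators follow the train/test
discipline strictly: anything learned — feature retention, imputation
medians, standardization, tertile cutoffs, the penalty, the baseline
hazard — is computed on training samples and applied to test samples
without re-estimation.

## Partial likelihood and tie handling

All likelihood-based components (the path solver, the unpenalized
Newton fitter, the Breslow baseline) share the Breslow convention for
tied event times: every death at a tied time uses the full risk set.
This keeps the penalized objective, its KKT certificate and the
baseline hazard mutually consistent. Efron or exact corrections are out
of scope. The k-sample log-rank test is delegated to lifelines'
`multivariate_logrank_test`; p-values are upper-tail chi-square with
k−1 degrees of freedom and no multiplicity correction is applied at the
stratification step.

The unpenalized fitter is a damped Newton iteration on the negative log
partial likelihood, run to gradient sup-norm ≤ 1e-8, with standard
errors from the inverse observed information. Monotone likelihood is
detected two ways: diverging coefficients during iteration, and a
converged solution whose standardized effect |β|·sd(x) exceeds 15
(hazard ratios beyond e¹⁵ per standard deviation do not occur in real
cohorts; a vanishing gradient there signals a likelihood supremum at
infinity, not an estimate). Both raise `ConvergenceError` rather than
returning silently.

## The penalized path

Objective: −log L(β) + λ‖β‖₁ + λ₂‖β‖₂² on per-feature standardized
covariates (mean 0, variance 1 on the fitting data; the transform is
stored and reused for any later cohort). Standardization is required
because the L1 penalty is scale-sensitive. Constant columns are
unidentifiable under the partial likelihood and are dropped with a
logged warning.

* **Grid.** 100 points geometrically spaced from λ_max down to
  0.001·λ_max, plus λ = 0 when p < n. λ_max is the sup-norm of the
  score at β = 0, so the first grid point is exactly the zero vector.
* **Solver.** Proximal Newton: the outer loop forms the usual
  diagonal (IRLS) quadratic approximation of the Breslow partial
  likelihood; an inner cyclic coordinate-descent kernel (numba-compiled,
  glmnet-style active-set sweeps) solves the penalized weighted least
  squares; step halving guards descent of the true penalized objective.
  Solutions are warm-started along the grid. The predictor–corrector
  step-size machinery of the original path-following formulation is not
  reproduced: only the solution path is consumed downstream, and the
  coordinate-descent solutions satisfy the same KKT system.
* **Certification.** A grid point is flagged converged only when the
  KKT violation of the penalized objective is ≤ 1e-6. Points where the
  violation stops contracting (three consecutive iterations without a
  30% reduction), or where the linear predictor spread exceeds 15 (a
  saturated, perfectly-ordered fit with p ≥ n), are abandoned and
  flagged unconverged; the path is still returned. This happens only in
  the deep-overfitting tail of the grid on p ≥ n data, where no
  meaningful solution exists.
* **λ₂** defaults to 1e-5 — small enough to be negligible when
  covariates are weakly correlated, large enough to remove degeneracy
  among strongly correlated ones. Configurable.

## Concordance probability

The concordance probability estimate (CPE) of a fitted Cox model is a
function of the linear predictors alone: a pair with scores η_i ≠ η_j
contributes the model-implied probability 1/(1 + exp(−|η_i − η_j|))
that the higher-risk member fails first. The exact form averages this
over informative (untied) pairs; tied pairs assert no ordering and are
excluded, and a cohort where all pairs are tied is a random predictor
with CPE 0.5 by definition. This tie convention makes the two analytic
benchmarks exact: an all-identical cohort scores exactly 0.5 and two
groups separated by a 100-unit margin score 1.0 to machine precision.
A smoothed form replacing the pair indicator with Φ(−x_ij/h) is
provided (reference bandwidth 0.5·sd(η)·n^(−1/3)); the exact form is
the default everywhere. Because the estimate depends only on unordered
pairwise score gaps, it is invariant under sign flips of the predictor:
direction information comes from the fitted coefficients, not from the
estimate.

**Validation CPE.** The raw estimate grows with the spread of the
index regardless of whether the index carries outcome information, so
it cannot score held-out data as-is — it would always reward denser,
more overfit models. Held-out evaluation therefore anchors the index to
the held-out outcomes: the index is standardized, a single Cox
calibration coefficient γ is refit on the held-out cohort, and the CPE
of γ·η is reported. An uninformative index yields γ ≈ 0 and a score
near 0.5; the zero model yields exactly 0.5; a separating index caps γ
at 50 and scores near 1. Harrell's C (via scikit-survival) is kept as
an independent, outcome-based concordance oracle in the test suite and
is never used in the fitting path.

## Cross-validated penalty selection

Two-fold cross-validation repeated 10 times. The λ grid is computed
once on the full training cohort and shared across folds; each fold
refits the path (including standardization) on its in-fold half and
scores every grid point by the validation CPE of the held-fold index.
Folds are redrawn (bounded retries) until both halves contain at least
two events. The selected λ maximizes the mean of the 20 held-fold
scores; exact ties resolve to the largest λ (sparsest model). The split
into train/test cohorts is simple random with n_train = ⌊n·fraction⌋
(default 0.8); an event-stratified variant is available.

## Prognostic scores and prediction

The c-score is the signature's linear predictor on standardized values;
the t-score is the mean over poor-prognosis features (β > 0) minus the
mean over good-prognosis features (β < 0), also on standardized values
(the fitted coefficient sign is the only direction label available).
Tertile cutoffs use linear-interpolation quantiles of the training
scores at 1/3 and 2/3, ties assigned to the lower stratum. The hazard
ratio compares high vs low strata only (intermediate excluded) via an
unpenalized Cox fit on the group indicator, with Wald 95% CI
exp(b ± 1.96·se). Predicted median times are read off the Breslow
baseline at observed-event-knot resolution (no interpolation between
knots — the baseline is a step function); a curve that never reaches
0.5 within follow-up reports "not reached". Because S(t|x) is monotone
in η, predicted medians are automatically anti-monotone in the c-score.

Degenerate evaluations are defined rather than crashed: an empty
signature gives a constant index, no stratification, log-rank p = 1 and
CPE 0.5.

## Feature ranking

Individual stratification power is the 3-group log-rank statistic on
the feature's bottom-15% / middle / top-15% split (linear-interpolation
quantiles, ties to the lower group), ranked by descending chi-square
with feature-id tie-breaks. Ranking uses the full provided cohort by
default. The split is rank-based, so ranking is invariant under
strictly increasing transforms of any single feature.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Coupling.** Per gene, a latent standard normal drives mRNA; matched
  copy-number, methylation and targeting-miRNA columns mix in fresh
  Gaussian noise at the Pearson level 2·sin(π·ρ_s/6), which hits the
  signed Spearman target ρ_s exactly in expectation and survives every
  monotone marginal transform. Methylation latents are squashed through
  a logistic to (0, 1); mRNA gets gene-specific location/scale;
  copy-number is centered at 0. Default targets: ρ = +0.6 (CNA), −0.5
  (methylation), −0.3 (miRNA) — signed couplings of realistic magnitude
  for regulatory relationships.
* **Survival.** Event times are exponential with rate h₀·exp(η),
  h₀ = 1/baseline_scale; the exponential baseline gives closed-form
  medians (ln 2 · scale) used as test oracles. Censoring is uniform on
  (0, τ), independent of covariates, with τ calibrated by bisection so
  the expected censored fraction of the drawn cohort matches the
  target. Defaults: 481 patients, 45% censoring, baseline scale 60
  months — an advanced-carcinoma-sized cohort with median follow-up of
  order tens of months. Simulated ties are broken by a deterministic
  1e-9-month jitter so tie conventions never matter downstream.
* **Ground truth.** A sparse causal set (default: 10 features spread
  4/3/2/1 over mRNA/methylation/CNA/miRNA on distinct genes,
  alternating signs, |β| = 0.5 per standard deviation) acts through the
  standardized combined feature space; the true linear predictor is
  stored with the cohort.

What the generator does **not** emulate: platform artifacts (batch
effects, probe-level noise, realistic missingness), heavy-tailed or
multimodal expression marginals, non-proportional hazards, informative
censoring, and network-structured effects. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated model, not performance on TCGA-like data.

## Problem sizes and numerical choices

Simulation-backed checks run at the sizes their claims need: copula
coupling at n = 500 (±0.07 on Spearman), coefficient recovery at
n = 1000 (±0.1), the Breslow/median closed forms at n = 2000–3000, and
the full-study recovery and null-calibration checks at n = 300 with 200
combined features over 20 seeds. Every randomized step consumes an
explicit seed; identical configurations reproduce bit-identical
artifacts.

## Known limitations

* The paths are meaningful only down to the overfitting boundary on
  p ≥ n data; the deep tail of the grid is flagged unconverged there.
* No time-varying covariates, competing risks, or calibration-curve /
  time-dependent-ROC evaluation.
* miRNA pairing relies on a supplied target table; no de novo
  all-pairs target scanning.
* The validation CPE's calibration step treats the index as the single
  covariate of a Cox model on the held-out cohort; with fewer than two
  held-out events it falls back to 0.5.
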