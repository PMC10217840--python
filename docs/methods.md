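# Methods

This note documents the statistical machinery of `steroidopls`, the
choices made where the design was genuinely open, and what the packaged
synthetic cohorts can and cannot establish.

## Cohort model

A cohort is a per-subject table with sex (F/M), age (years), a
diagnostic cell label in A±D± notation that decomposes into two binary
factors (AD, T2DM), and measured variables declared in a packaged data
dictionary (`src/steroidopls/data/variables.json`): anthropometry,
glucose metabolism, lipids, liver enzymes, thyroid hormones, renal
markers, SHBG, and 42 steroid analytes in nmol/L. Derived indices use
the standard published forms: BMI = weight/height², WHR = waist/hip,
BAI = hip/height^1.5 − 18 (hip in cm, height in m), HOMA R =
glucose·insulin/22.5, HOMA F = 20·insulin/(glucose − 3.5) (undefined at
glucose ≤ 3.5 mmol/L; the cell is left missing with a logged warning),
and Friedewald LDL = TC − HDL − TG/2.2 (all mmol/L). `derive_indices`
never overwrites a populated cell, so it is idempotent and measured
columns are authoritative.

Missing data are handled complete-case **per model**: a subject is
dropped from a given ANCOVA or OPLS fit only if it misses a variable
that fit uses, and every result object records its effective n. This is
the simplest policy consistent with per-model evaluation counts smaller
than the group sizes.

## Power transformation

Family: one-parameter Box-Cox with an automatic shift
(`1e−6 − min(x)`) when values are non-positive. The exponent maximises
the Box-Cox profile log-likelihood over λ ∈ [−3, 3], by a 121-point
grid followed by golden-section refinement to 1e−4 — deterministic, and
checked in the tests against an exhaustive 0.01-grid oracle. λ is
fitted once per variable on each sex's pooled data (all four groups
together), since the screen transforms each variable once; fitting per
group would break the comparability of group means. λ = 1 is treated as
the affine case x − 1 (defined on all reals); elsewhere the Box-Cox
domain x + shift > 0 is enforced. Forward/inverse transforms use
expm1/log1p so round trips hold to 1e−9 relative error throughout the
numerically well-conditioned region |λ·ln x| ≲ 14 that fitted
transforms occupy.

"Retransformed" summaries (means, CI endpoints) are computed on the
transformed scale and mapped back through the strictly monotone
inverse, so interval ordering is preserved and log-scale intervals are
right-skewed, as expected.

## ANCOVA screen

Per variable: ordinary least squares on the transformed scale with
sum-to-zero factor coding, Type III (marginal) sums of squares — the
appropriate choice for this unbalanced factorial, and the default of
the commercial package this analysis style comes from. Adjusted group
means are the model predictions at the per-sex mean age (the covariate
evaluation point is not otherwise canonical); their 95% CIs are t-based
prediction intervals of the mean, back-transformed. Age itself is
screened with the same factorial model without the covariate. The six
pairwise contrasts are differences of adjusted means using the model's
residual variance, each tested at α/6 = 0.00833; Bonferroni is applied
per variable (6 contrasts), with no across-variable multiplicity
control, mirroring the screen it reproduces. Degenerate inputs: an
empty group cell raises naming the cell; a constant age column drops
the covariate rather than fitting a singular design; per-variable
failures inside the full screen are collected, not fatal.

## OPLS discriminant

Classes are coded 0/1 and centred. With X standardized (mean 0, unit
SD, ddof = 1), the predictive weight is w = Xᵀy/‖Xᵀy‖; each orthogonal
component removes from the current X-loading its projection on w
(Trygg–Wold), deflating X by t₀p₀ᵀ. With K = 0 the model reduces
exactly to single-component PLS1, which the tests verify against a
brute-force oracle. Reconstruction X = T_pP_pᵀ + T₀P₀ᵀ + E is exact by
construction and asserted to 1e−8; T₀ ⟂ T_p likewise.

* **Orthogonal-component count**: start at K = 0 and accept K+1 only if
  cross-validated Q² improves by more than `q2_tol` (default 0.01),
  capped at min(n−2, p−1, 5).
* **Cross-validation**: stratified 7-fold with seeded round-robin
  assignment after a seeded shuffle; folds that would lose a class
  reduce the fold count with a warning. Q² = 1 − PRESS/SS on the coded
  outcome; standardization and weights are re-estimated inside each
  training fold.
* **VIP pruning**: VIP_j = √(p·Σ_a SSY_a(w_ja/‖w_a‖)²/Σ_a SSY_a), which
  for the single predictive component is √p·|w_j| with mean VIP² = 1.
  Predictors with VIP below threshold 1.0 are removed and the model
  refitted, iterating until all survivors reach the threshold, with two
  guards: a refit that would cost more than `q2_tol` of Q² is rejected
  (the previous model is kept), and VIPs within 0.1 of the threshold
  are retained — in a block of equally informative predictors the VIPs
  scatter tightly around 1 and a hard cut would eliminate half of them
  by sampling noise alone. Pruning to an empty set raises.
* **Homogeneity screen**: once, before the final fit, Hotelling
  T² = (s−s̄)ᵀS⁻¹(s−s̄) on the leading two principal-component scores
  of standardized X, against the F-based 95% limit
  d(n−1)(n+1)/(n(n−d))·F₀.₉₅(d, n−d); flagged subjects are excluded and
  logged, unless exclusion would leave fewer than 3 subjects in a
  class.
* **LLR calibration**: univariate logistic regression of class on t_p
  maps the score to the log likelihood ratio, capped at ±15; the
  probability is the logistic map of the capped LLR, and the bijection
  p = e^LLR/(1+e^LLR) is asserted to 1e−12. Under complete separation
  the slope diverges, so the calibration pivots on the separating
  midpoint with the nearest training subject placed exactly at the cap.
* **Loading statistics**: per-predictor loadings are reported as
  correlations with the predictive component (R). Their t-statistics
  are jackknife estimates over the CV folds (SE from the leave-fold-out
  loadings); the published tables' t recipe is not documented, so no
  numeric agreement with any external t values is promised — only the
  R column and its significance pattern.
* **Evaluation**: confusion at probability 0.5 (a tie counts as
  negative — documented, configurable at the caller level), sensitivity
  on cases and specificity on controls with unclipped Wald intervals
  p ± 1.96√(p(1−p)/n). Unclipped is deliberate: near-perfect
  classifiers on small groups legitimately print bounds slightly
  outside [0, 1], and clipping would silently change the convention the
  reference tables use. Both in-sample and cross-validated evaluations
  are available; report footers use in-sample.

## Synthetic cohort generator

The generator is calibrated to the published group statistics:
per-sex group sizes (women 41/41/47/7; men 18/33/25/7 across
A−D−/A+D−/A−D+/A+D+), per-variable per-group retransformed means with
95% CIs, and per-model component loadings. For subject i of group k and
variable j the transformed-scale value is

    z_ij = μ_jk + σ_jk · (b_j·u_i + √(1 − b_j²)·ε_ij)

with u_i ~ N(0,1) a latent class-axis position shared by all of the
subject's variables, ε white noise (optionally Student-t standardised
to unit variance, for robustness experiments only), and b_j =
`class_axis_strength`·R_j from the configured model's loadings. σ_jk is
recovered from the printed CI as h·√n/t₀.₉₇₅,ₙ₋₁ with h the
transformed-scale half-width; the A+D+ cells (n = 7) use the same
formula with 6 degrees of freedom. The transform hint is natural log
for concentration-like variables (steroids, SHBG, enzymes, most
biochemistry) and identity for age, anthropometric indices, ratios and
blood pressure; the fitted λ of the original data is unknowable, and
the hint is stored per variable and overridable.

What the generator does **not** model: between-variable correlation
beyond the single class axis, assay error, age–analyte coupling within
groups, drug-treatment effects, and any real covariance structure among
steroid pathway neighbours beyond what one axis induces. Consequently,
passing tests demonstrate that the pipeline recovers the structure it
assumes (marginal group separations, one shared latent axis) — not that
it would behave identically on the original cohort. Two documented
approximations matter quantitatively: the printed CIs belong to
age-adjusted means, so treating them as raw within-group CIs slightly
inflates the derived σ; and because within-group age is independent of
every analyte, the age covariate in the screen is pure noise whose
fitted slope mildly erodes contrast power. Both effects are bounded in
the test suite (pairwise-contrast recovery rates, Monte-Carlo F
recovery within ±40%).

## Problem sizes and determinism

Stochastic checks use fixed seed ranges and moderate replicate counts
chosen to keep the whole suite in the minutes range on one CPU: 200
replicates for contrast-recovery and F-recovery runs, 100 for
pruning/sign-recovery constructions, 50 datasets for the Q² ≤ R²Y
sweep, multiplier 100 (≈ 13,600 subjects) for generator marginal
fidelity at ±2%. Every random draw flows from an explicit seed
(`numpy.random.default_rng`); rerunning any stage with the same seed
and input reproduces its outputs byte-for-byte, which the tests assert
for the generator, the screen and the pipeline bundle.

## Known limitations

* Single predictive component only (binary outcomes); no multi-class
  OPLS, O2-PLS or kernel variants, and no attempt to match any
  commercial implementation bit-for-bit.
* The jackknife-over-folds t-statistics are internally consistent but
  not comparable across CV schemes.
* The VIP guard band (0.1) and the Q²-gain rule (0.01) are pragmatic
  SIMCA-style defaults, exposed in `OplsConfig`.
* ANCOVA CIs are t-based; whether the reference tables used t or normal
  quantiles is not recorded, and the difference is within rounding at
  these group sizes.
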