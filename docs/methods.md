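# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the places where the design was genuinely open.

## The location–scale waveform model

Power `y_ij` (subject *i*, cycle point *j*, W/kg) follows a two-parameter
location–scale family: `y ~ D(mu, sigma)` with `mu` an additive predictor
and `sigma = exp(eta_sigma)` so the scale is positive by construction.

**Mean predictor.** Intercept; a dummy-coded sex effect (female 0, male 1);
study- and subject-level random intercepts; and penalized smooths of cycle,
age, speed, height and stride length, plus tensor-product interactions (the
candidate set is the eleven terms in `gaitspan.gamlss.CANDIDATE_TERMS`).
The model assumes waveform variation across the cohort is a smooth function
of these covariates plus additive subject/study offsets; it does not model
within-subject stride-to-stride dynamics (the input is one averaged
waveform per subject and joint).

**Scale predictor.** Intercept plus a cubic regression spline of the cycle
point, for every joint. Exploratory residuals of constant-variance fits
vary chiefly along the cycle — spread is largest around push-off — so the
cycle is the single variance covariate; `sigma` is floored at 1e-6 W/kg so
the likelihood stays finite in perfect-fit limits.

**Families.** normal, scaled-t (fixed degrees of freedom, default 10),
logistic, Gumbel and skew-normal (fixed shape), behind a registry
(`register_family`) for extensions. Shape parameters are fixed, not
estimated: the scale model machinery stays two-parameter. Expected
(Fisher) weights for the scoring updates are computed once per family by
numerical integration over the standard variate.

## Basis construction

* **Cubic regression splines**: natural-spline basis parameterized by its
  values at `k` knots placed at quantiles of the unique covariate values
  (evenly spaced order statistics, so knots are strictly increasing), with
  the exact integrated-squared-second-derivative penalty. Evaluation
  outside the knot range extends linearly. Each smooth block carries a
  sum-to-zero constraint over the training data, so the penalty null space
  after centering is one-dimensional (the linear trend).
* **Tensor products** are interaction-only: each margin is sum-to-zero
  constrained *before* the row-wise Kronecker product. This matters because
  the hierarchy rule guarantees a tensor always coexists with its
  univariate parents, and an unconstrained product block contains
  penalty-free main-effect directions that make the penalized system
  exactly singular next to them. One penalty (and smoothing parameter) per
  margin, Kronecker-expanded with identities.
* **Random intercepts** are ridge-penalized indicator columns — equivalent
  to i.i.d. Gaussian random effects at the level of point predictions, with
  the smoothing parameter playing the role of the variance ratio.

## Fitting

Rigby–Stasinopoulos-style backfitting: penalized weighted least squares on
the working response of the mean given the current scale, then of the
log-scale given the current mean, until the penalized log-likelihood
changes by less than 1e-6 (at most 200 outer iterations; non-convergence is
an error carrying the trace). Smoothing parameters are chosen by GCV on the
working model — a coordinate-descent search over a log-spaced grid, with
cross-products formed once so each candidate costs one Cholesky solve —
during the first outer iterations (default 2) and frozen afterwards. After
the freeze the objective is fixed and monotonicity is enforced by
step-halving. `vcov_mu` is the Bayesian posterior covariance
`(X'WX + sum lambda_i S_i)^{-1}` at the final weights.

When smooth columns lie numerically in the span of penalized indicator
columns (age is constant within subject, so an age spline is spanned by
subject indicators), the penalized information matrix is positive definite
but borderline; a relative diagonal jitter of 1e-10 is applied before
declaring the system singular.

## Selection

The structure search is Bayesian optimization over per-term states (removed,
or a vector of per-margin basis dimensions, bounds 3–25): a Matern-5/2
Gaussian process on a scaled integer encoding (a presence flag plus
normalized k per margin), expected-improvement acquisition over 500 sampled
hierarchy-repaired candidates per iteration, a random initial design of 20
valid configurations, and outright enumeration whenever the space is no
larger than the budget. Proposals violating the hierarchy (an interaction
present with a parent removed) are repaired by removing the orphaned
interaction — never by adding terms — so repair is idempotent. The
objective is held-out relRMSE: a subject-level split (two-thirds train by
default; subjects never straddle the split, since cycle points within a
subject are dependent), models fitted under a scaled-t working distribution,
errors normalized per waveform by the observed range and averaged. Failed
fits score +inf and can never be selected. The default budget is 60
evaluations, a desk-scale setting; larger budgets are a parameter.

relRMSE's denominator is configurable in principle (range is the
convention adopted here); the estimates it ranks are population-level
predictions with study effects included and unseen-subject effects at zero.

**Distribution comparison** fixes the selected predictors and refits each
candidate family on the training split. By default the smoothing parameters
are also fixed — chosen once under the working family and reused — so the
comparison isolates the distributional assumption rather than re-running the
smoothness choice per family. A caveat established by simulation in this
package: when the residuals really are Gaussian and the mean/variance model
is well specified, the normal, scaled-t and logistic fits are numerically
near-identical (paired held-out relRMSE differences of order 1e-5 against a
replicate spread of order 3e-4), so the selected family among symmetric
candidates is close to a coin flip; the comparison is informative mainly in
the heavy-tailed direction, where the scaled-t's bounded score visibly
improves the held-out mean fit. Family-selection simulations therefore use
homogeneous cohorts (zero study/subject random-effect SDs) and a small
training fraction (1/4): family discrimination concerns the residual
distribution, and unpredictable held-out subject offsets otherwise dominate
the paired comparison.

## Inference

* **Partial effects**: a univariate smooth's block evaluated on a grid,
  with pointwise 95% CI from the block's sub-covariance. The sum-to-zero
  constraint centers it over the training covariate distribution. Note the
  estimand: under cycle-dependent residual variance, the additive `f(age)`
  converges to the *precision-weighted* cycle average of a
  cycle-localized age effect.
* **Marginal age profile** (`marginal_age_profile`): the predicted mean
  waveform averaged uniformly over the cycle at each grid age, centered.
  This estimates the unweighted cycle-marginalized age effect — the
  quantity the synthetic ground truth defines — and is the recommended
  recovery diagnostic when the model contains cycle-age interactions.
* **Predicted waveforms**: one per (speed, age) of the grid — defaults
  1.0/1.5 m/s by 20…80 years at stride length 1.5 m — with random effects
  at zero (population level), sex at 0.5 (average over the two levels) and
  height at the training mean; all configurable, as these reporting
  settings are conventions, not estimates. Ankle predictions exist on
  points 21–69 and are zero-padded and flagged outside.
* **Peaks**: A2 (window 40–65), H1 (0–25), H3 (45–70) — windows are
  standard burst timings and configurable — extracted as the windowed
  maximum of the predicted mean (ties to the earliest point). CIs come from
  1000 seeded draws of the coefficient vector from `N(beta_mu, vcov_mu)`,
  re-extracting the maximum per draw: the maximum is non-smooth, so a
  delta-method interval would be unreliable.

## The synthetic cohort generator

Four studies emulate a pooled overground/treadmill cohort: per-study age
ranges and truncated-normal age, height and mass distributions, sex ratios,
and a walking-speed model with an inverted-U over age peaking near 30 years
(study-specific level, configurable); stride length is linear in speed and
height. Defaults (25 subjects per study, i.e. 100 subjects) are in
`default_studies()`.

Waveforms are sums of Gaussian bumps at canonical burst locations (A1/A2
for the ankle, K1–K4 knee, H1–H3 hip) whose amplitudes vary smoothly with
age and speed: the ankle push-off amplitude peaks at age 55 with curvature
5e-4 W/kg/yr² (roughly a 30% decline from peak to the oldest ages, matching
the aging literature), the knee late-stance absorption deepens by 0.02
W/kg/yr (a ~0.2 W/kg shift in mean knee power across the lifespan), and the
hip bursts scale strongly with speed (H1 ≈ 0.76, H3 ≈ 1.35 W/kg per m/s).
Study and subject effects are additive intercepts (SD 0.05 and 0.10 W/kg);
an optional smooth per-subject curve perturbation exists but defaults to
off, since the model consumes stride-averaged waveforms with subject-level
intercepts. Residuals are `sigma(cycle)` times a standard normal (or
Student-t, for heavy-tail experiments) draw, with `sigma(cycle)` largest
around push-off (base 0.15 W/kg scaled by a 0.6–1.8 multiplier).

What the generator does **not** emulate: within-subject stride dynamics,
non-additive study effects (treadmill vs overground beyond an intercept),
marker noise or inverse-dynamics error, asymmetry between limbs, and any
non-smooth age effects. Passing tests therefore demonstrate that the
pipeline recovers truth under its own statistical assumptions at realistic
magnitudes — not that those assumptions hold for any particular real
cohort.

Raw per-stride fixtures (`sample_raw_strides`) carry the assigned waveform
in the moment's first component against unit angular velocity, with a
vertical GRF that is zero in swing and rises above 100 N at each initial
contact, so the preprocessing chain (dot product → threshold events →
101-point normalization → mass normalization → averaging) reproduces the
assigned waveform to within interpolation error (< 0.05 W/kg at 100 Hz).

## Preprocessing conventions

Linear interpolation for the 101-point time normalization (the dominant
convention, and exactly testable); threshold crossings with a closed lower
bound (≥ threshold counts as contact) for deterministic ties; per-study GRF
thresholds 10/50/20/20 N supplied via configuration; "points 21 to 69" read
as 0-based percent-of-cycle indices (the bound is configurable, since a
1-based reading would shift the window by one point). The zero-lag
Butterworth filter interprets its order as the effective two-pass order
(order 4 = a 2nd-order design applied forward and backward). No automatic
stride-quality rejection beyond finiteness checks.

## Problem sizes and determinism

Default experiment sizes are desk-scale study conditions: 100-subject
cohorts for recovery checks, 60-evaluation optimization budgets, 10–20
replicate simulations for rate-based checks. All randomness flows from
explicit integer seeds; pipeline stages derive their seeds as a stable hash
of the global seed and the stage name, so full runs are byte-identical in
their JSON outputs at a fixed configuration.

## Known limitations

* Shape parameters of the families are fixed, not estimated, and only the
  mean and scale get predictors.
* GCV on the working model is a pragmatic smoothing-parameter choice; it
  can over-penalize smooths that compete with random effects for
  subject-constant covariates (which is why recovery diagnostics use the
  prediction-marginalized profile).
* The cycle smooth is not cyclic even though waveforms are periodic; with
  the stride cut at initial contact the endpoints need not match exactly,
  and a non-cyclic basis was retained deliberately.
* Confidence intervals condition on the selected structure and smoothing
  parameters; selection uncertainty is not propagated.
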