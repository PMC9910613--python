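# Methods

## Scope and model

`qgdiv` quantifies how standing genetic variation within populations
predicts phenotypic divergence among populations, on proportional scales
that make both comparable across traits and species.

**Evolvability.** For a trait with additive genetic variance V_A and mean
x̄, the mean-scaled evolvability is I_A = V_A / x̄² — the expected
proportional response to one episode of unit-strength selection.  For a
multivariate phenotype with mean-scaled G-matrix **G**, the evolvability
along a unit direction **v** is e(**v**) = **v**ᵀ**G****v**, and the
conditional evolvability — the response when all orthogonal trait
combinations are held constant by stabilizing selection — is
c(**v**) = (**v**ᵀ**G**⁻¹**v**)⁻¹.  For any direction
0 ≤ c(**v**) ≤ e(**v**), with equality exactly at eigenvectors of **G**.

**Divergence.** Per trait, d is the variance of ln population means
(unbiased, n−1 denominator); multivariately, **D** is the covariance
matrix of ln population means, and the divergence along **v** is
d(**v**) = **v**ᵀ**D****v**.  The folded-normal back-transform
d_P = exp(√(2d/π)) expresses d as the expected multiplicative deviation
of an average population from the grand mean (d_P = 1.064 at
d = exp(−5.11)).

**Meta-regression.** The univariate analysis regresses ln d on ln e in a
weighted Gaussian mixed model: weights are inverse sampling variances of
ln d (delta method: var(ln d) ≈ 2/(n_pop + 2), from
σ²_m(d) = 2d²/(n_pop + 2)); random intercepts for species and divergence
study; a random slope for ln e per study whose SD quantifies slope
heterogeneity; ln(n_pop) and ln(max geographic distance) as centered
fixed covariates, so the intercept refers to average covariate values.
Because the predictor is itself an estimate, the fitted slope is biased
toward zero; it is corrected by dividing by the reliability 1 − V_me/V,
where V_me is the error variance surviving in the per-pairing mean log
evolvabilities (mean within-species-by-trait variance of repeated log
estimates divided by the number of repeats) and V the variance of the
predictor.  The corrected slope's SE is the raw SE divided by the same
reliability; uncertainty in the reliability itself is neglected, which is
accurate when many species-trait units contribute.

The scaling exponent links to macroevolutionary models: neutral
divergence gives d = 2V_m t and equilibrium e = 2V_m N_e, hence
d/e = t/N_e for every trait and a log-log slope of exactly 1; an
optimum tracked with a lag under weak stabilizing selection
(Ornstein–Uhlenbeck moving optimum) gives slopes between 0.5 and 1.

## The mixed-model engine

No Python mixed-model implementation exposes per-observation residual
weights (σ²/w_i) together with crossed scalar random terms, so the
engine is implemented directly (`lmm.py`): the profiled (RE)ML deviance
over log variance ratios θ_q = ψ_q/σ², with β and σ² profiled out in
closed form and all solves reduced to the q×q scale by the Woodbury
identity (q = total random-effect levels).  Optimization is Nelder–Mead
from two starts (θ = 1 and θ ≈ 0.05); variance ratios below e⁻¹² are
flagged as boundary fits.  The engine reproduces `lme4::lmer`
(ML and REML, weighted, random slopes) to ~5 significant digits on
fixture data, and collapses exactly to OLS/WLS without random terms.
ML is used whenever AIC is compared across fixed-effects structures
(REML likelihoods are not comparable there); REML is available for final
variance reporting.  AIC = −2ℓ + 2(p + Q + 1).

Marginal/conditional r² follow the variance-partition convention for
Gaussian mixed models: r²_M = var_fixed / (var_fixed + var_random +
var_resid), with random-slope contributions evaluated at the observed
covariate distribution (ψ·mean(z²)) and the weighted residual variance
summarized as σ²·mean(1/w).

Moderator (slope-heterogeneity) models add the focal factor's main
effect plus its interaction with ln e, treatment-coded against the
alphabetically first level unless a reference level is configured;
support is judged by ΔAIC = AIC_complex − AIC_baseline with |ΔAIC| > 2
labeled detectable.

## Multivariate analyses

Each "case" pairs a G-matrix with a D-matrix (optionally a P-matrix)
over ≥3 shared traits.  Within a case, ln d(**v**) is regressed (OLS) on
ln e(**v**) over four direction sets: the original trait axes (reducing
to the matrix diagonals), and the eigenvectors of **G**, **D**, or
**P**.  Eigenvectors are reported with descending eigenvalues and the
sign fixed so each vector's largest-magnitude coefficient is positive.
Directions with non-positive projected variance (possible for indefinite
sample matrices) are dropped with logged counts.

Sampling uncertainty: **G** is resampled by drawing n_families
observations from MVN(**1**, **G**) per iteration (1,000 by default) and
taking the sample covariance — reproducing the design's sampling noise,
including the upward bias of the leading eigenvalue.  When only a
point-estimate **D** is available its draws follow a Wishart with
effective df = n_pops − 1 (an approximation to the error-corrected
posterior used with raw data, which is out of scope).  The slope SE is
the SD of regression slopes over randomly paired (G, D) draws (1,000
pairings by default), with directions recomputed per draw from the drawn
matrix that defines the direction set; a toggle holds directions fixed
for sensitivity analysis.

These sampling errors bias the slopes in opposite directions: error in
**D** inflates the spread of the response along D-eigenvectors (upward
bias), error in **G** dilutes the regression along G-eigenvectors
(downward), while P-directions are unbiased to the extent that error in
**P** is independent of both.  The package's synthetic noisy-matrix
ensembles reproduce this D > P > G ordering of grand slopes.

Grand slopes per direction set come from an intercept-only weighted
mixed model over cases (weights = inverse squared slope SE; random
intercepts for species and D-matrix identity when ≥2 levels each).

## Divergence vectors

From each study's designated focal population (the population carrying
the G-matrix) to every other population, Δ = ln x̄_target − ln x̄_focal;
its norm is the divergence magnitude and e(Δ/‖Δ‖), c(Δ/‖Δ‖) are compared
with the matrix summaries ē = trace(**G**)/k and c̄ (the seeded
Monte-Carlo mean of c(**v**) over uniform random unit directions —
10,000 by default; the closed-form average is not used as the primary
path).  Reported are the proportions of populations with
e(Δ)/ē > 1 and c(Δ)/c̄ > 1, error-weighed mean log ratios (sampling
variances from the G resampling draws; intercept-only mixed model with
random intercepts for G-matrix and population identity), and per-study
rank correlations between divergence magnitude and e(Δ) — positive when
populations diverging along more evolvable directions diverged farther.
Display scaling for summary figures maps values into [−1, 1] piecewise
linearly between ē and e_min / e_max.

## Synthetic worlds

The generator emulates a comparative plant database: species carry
Wishart-distributed G-matrices (compound-symmetry expectation,
correlation 0.3; trace/k rescaled to the target mean evolvability,
default 0.005) and contribute divergence studies of 7–13 populations.
Defaults mirror the structure of published compilations: 2 studies per
species (real compilations run ~1.5; more studies per species makes the
shared species-level predictor noise correlated across many rows and
degrades the corrected-slope CI calibration), n_families = 50,
30 individuals per population, 3 repeated evolvability estimates per
trait with log-normal error SD 0.3, heritability 1/3 linking P = G/h²,
and ~70% floral traits with vegetative among-population variance
inflated 5× (yielding median d_P ≈ 1.06 floral vs ≈ 1.13 vegetative,
matching observed contrasts).

Divergence models: *neutral* draws ln population means from
MVN(0, r_j·**G**) with study multipliers r_j log-normal around t/N_e
(SD 0.5 on the log scale, mean-centered so E[r_j] = t/N_e exactly);
*ou* keeps **G**'s eigenvectors but maps eigenvalues through a power law
λ^s (s ∈ [0.5, 1], default 0.7), the stationary among-population
covariance of an OU-tracked optimum — s = 1 recovers neutral scaling.
Trait-category multipliers rescale the among-population covariance rows
and columns.  Per-population sampling noise of variance P_ii/n on the
log scale is added; geographic coordinates are drawn with spread
increasing with r_j so that maximum great-circle distance is an
informative covariate.  Coordinates are covariate generators only — no
isolation-by-distance genetics is simulated, no gene flow, and no
explicit mutation–drift individual-based dynamics.  With
`exact_matrices=False` the stored G- and P-matrices are re-estimated
from finite samples, reproducing realistic eigenvalue biases.

What passing tests on these worlds do *not* show about real data: real
compilations have unbalanced trait sets, missing matrices,
non-log-normal measurement error, correlated category and evolvability
differences, and phylogenetic structure; none of these are emulated, so
recovery results certify the estimators under the stated generating
model only.

## Numerical choices and problem sizes

- Matrix symmetry: construction tolerates relative asymmetry 1e-10; the
  CSV reader averages triangles up to 1e-8 (relative to max(|entry|, 1))
  and rejects beyond.
- Conditional evolvability errors out (no silent pseudo-inverse) when
  the reciprocal condition number of **G** falls below 1e-12
  (configurable) — silent regularization would bias c downward
  invisibly.  Direction vectors are auto-normalized, with a warning when
  the input length deviates from 1 by more than 1e-8.
- D-matrix estimation uses listwise deletion of incomplete populations
  (logged) by default; a strict mode errors instead.
- Bootstrap SEs for group medians of d_P: 2,000 seeded nonparametric
  resamples; singleton groups report an undefined SE.
- Statistical tests of Monte-Carlo unbiasedness use bounds calibrated
  for the number of correlated statistics examined (aggregate trace
  within 4 MC SEs, elements within 4.5) rather than a nominal 3-SE rule
  per entry, holding the joint false-alarm rate below ~0.1% without
  losing power against real biases.
- Recovery experiments run at 100 replicates of 200-study worlds
  (~1,200 paired observations per world) for CI-coverage checks, and
  40-case ensembles with 300 resampling draws/pairings for the
  bias-ordering checks; these sizes give Monte-Carlo error comfortably
  inside the tolerances tested.

## Known limitations

- The weights implementation (residual variance σ²/w_i) fixes the
  relative, not absolute, error variances — the meta-analytic
  convention; weights given as exact known variances are not supported.
- Wishart draws for point-estimate D-matrices understate uncertainty
  when population means are themselves noisy.
- The reliability correction treats V_me/V as known; its sampling error
  propagates to the corrected slope only through the point estimate.
- Interval-scale traits (e.g., phenology dates) cannot be mean-scaled
  and must be excluded upstream; divergence is raw, not
  time-standardized, so cross-study slope comparisons assume comparable
  divergence ages within studies.
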