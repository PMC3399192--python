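# Methods

## Model

`rrnorm` fits Gaussian linear mixed models for long-format repeated records
of a response trait against a covariate trait, the canonical case being
clutch size against laying date.

**Univariate stage.** Fixed effects: overall mean, a 3-level age factor
(classes 1, 2, 3+; the 3+ class is the reference so reported contrasts are
for first- and second-year breeders), and a linear covariate slope *b*
expressed per day on the median-centered date scale.  Random effects: an
i.i.d. year effect (trait rows only), an individual-specific polynomial in
the standardized covariate with unstructured coefficient covariance **G**,
and an i.i.d. residual.  The polynomial order is selected by fitting orders
0, 1, 2, ... stepwise (after a fixed-only and a +year baseline so the output
table mirrors the usual six-model layout) and testing each order against the
previous with a REML likelihood-ratio test on df equal to the number of new
(co)variances (x + 1 when moving to order x).  Selection stops at the first
non-significant step; AIC/BIC columns are reported for information only.
Fixed effects are identical across the ladder, so the REML comparisons are
valid; `compare_fits` refuses LRTs between fits whose fixed structures
differ.

**Covariate scaling.**  The covariate enters the random-regression basis
after the affine map t(d) = (d − mean)/(mean − min), fitted on the
*distinct* observed values so that "elevation" means the expected response
at the average of the covariate values (not the record-weighted average); a
`weighted=True` flag switches to record-weighted centering.  Under this map
the basis at t = 0 is the first unit vector, so G[0,0] is always the
among-individual variance at the covariate mean, and one unit of t equals
the distance from the mean to the earliest observed date.  The basis is raw
monomials by default because the coefficients then carry this direct
interpretation; a Legendre basis is available (`basis="legendre"`) for
conditioning at higher orders, with `legendre_to_monomial` providing the
exact coefficient back-transformation.

**Bivariate (selection) stage.**  One relative-fitness row per individual is
stacked below the trait records.  Fitness rows carry their own fixed effects
(mean + cohort-of-first-breeding factor, first cohort as reference) and load
on a single extra coefficient, the fitness elevation, extending **G** to
(k+2)×(k+2).  Because each individual contributes exactly one fitness
value, fitness slopes and a fitness residual are not estimable; both are
*structurally removed* from the likelihood rather than pinned to a small
constant (an `epsilon_fitness_resid` option reproduces the pinning behavior
of software that cannot constrain a residual to exactly zero; the default
epsilon recommendation is 1e-6 times the fitness phenotypic variance).  The
fitness row of the fitted joint matrix contains the selection differentials
S_p = cov(ind_p, w); gradients divide by var(ind_p), intensities by
sd(ind_p).  Significance of each S_p comes from refitting with that single
covariance constrained to exactly zero (1-df LRT).  The year effect loads on
trait rows only; annual variation in fitness is handled by the cohort fixed
effect.

**Nonlinear selection.**  The bivariate model estimates directional
selection only.  `blup_fitness_map` provides the usual graphical screen —
relative fitness against each property's BLUP with a descriptive quadratic
(optionally linear) least-squares overlay — and is labeled a diagnostic, not
a test: BLUPs are shrunken and conditioned on the model, so curvature in
this map is suggestive only.

## REML implementation

The restricted log-likelihood
−½[(n−p) log 2π + log|V| + log|X'V⁻¹X| + y'Py] is evaluated by exploiting
the covariance structure: conditional on year effects, individuals are
independent, so V = A + s2_year·Z_y Z_y' with A block-diagonal over
individuals.  Blocks (a handful of rows each) are Cholesky-factorized in
batch, grouped by block size, and the 31-ish dimensional year term is folded
in by a Woodbury identity; one likelihood evaluation costs
O(Σ n_i³ + n_years³) instead of O(n³).  Fixed-effect solutions and BLUPs
come from the same factorizations (equivalent to Henderson's mixed-model
equations); the BLUP of the year effect reduces to K⁻¹ Z_y'A⁻¹(y − Xβ̂)
with K = Z_y'A⁻¹Z_y + I/s2_year.

**Parameterization and optimization.**  G is optimized as its Cholesky
factor with logged diagonal (log-Cholesky), which enforces positive
semidefiniteness with an unconstrained smooth parameter vector; year and
residual variances are optimized on the log scale with bounds
[e⁻¹³·⁸, e⁸].  A parameter at the lower bound marks the fit as a boundary
case and suppresses SEs.  Optimization is L-BFGS-B with finite-difference
gradients (step 1e-7), ftol 1e-11, gtol 1e-6, max 500 iterations.  Default
is a 3-start search (moment-based partition of the OLS residual variance;
near-zero G; a seeded random perturbation); convergence is reported
honestly on the result and never raised as an exception.  The
single-covariance constraint is exact: coefficients are reordered so the
constrained pair occupies the two leading positions, where their covariance
is carried by the single factor entry L[1,0], which is dropped from the
parameter vector.

**Standard errors.**  The sampling covariance of the variance components is
the inverse of the central-finite-difference observed information of the
restricted likelihood at the optimum, mapped to the (co)variance scale by a
numerically differentiated Jacobian (delta method).  If the information
matrix is numerically singular the pseudo-inverse is used with a warning and
the fit is flagged non-identifiable (e.g. one record per individual aliases
the individual variance with the residual).  The variance-of-response
function v(t) = z(t)'Gz(t) gets delta-method bands from the same matrix:
SE² = a'Σa with a the gradient of v(t) in the unique elements of G; 95%
bands are ±1.96 SE with the lower bound floored at zero in reports (raw
values retained in machine-readable output).  Denominator df for
fixed-effect Wald tests are conservatively set to the number of individuals,
and labeled as such.

**LRT convention.**  Variance-structure LRTs use the plain chi-square with
df equal to the number of additional (co)variances.  This is conservative
when a variance sits on its boundary; `mixture=True` switches to the 50:50
chi-square mixture.  Negative statistics (numerical noise in nested
optimizations) are clamped to zero with a warning.

## Synthetic data generator

`simulate_dataset` draws from exactly the model above: joint coefficient
vectors (trait coefficients + fitness elevation) from a configured
(k+2)×(k+2) covariance, i.i.d. year effects and residuals, covariate values
as individual mean dates (SD 8 days) plus within-individual scatter (SD 6
days) — spans of roughly two months, as in long-lived owls — standardized by
the same rule the fitting stage uses.  Records per individual are
zero-truncated geometric (mean 3.1 by default), reproducing the heavy-tailed
mix of one-record and long-lived individuals; breeding years are consecutive
from a uniformly drawn cohort; ages progress 1 → 2 → 3+ from a sampled
first-record class.  Relative fitness is generated directly on the relative
scale: 1 + cohort effect (SD 0.1) + fitness elevation + independent noise,
floored at zero and renormalized to mean 1.

The owl-like default (`owl_like_config`) copies the motivating study's
structure: 361 individuals, 31 year levels, 3.1 records each, order-2 trait
polynomial, trait coefficient variances (0.141, 0.240, 0.975), year variance
0.156, residual 0.397, fixed mean 3.38 and slope −0.062/day, fitness
phenotypic variance 0.539 split into 0.439 elevation + 0.10 independent
noise, and the published property covariances (the combined matrix is
positive definite, eigenvalues 0.082–1.13).

**What the generator does not emulate.**  Real lifetime fledgling counts are
integers with a point mass at zero; the generator's floored Gaussian mimics
the zero mass but not the discreteness.  Flooring attenuates the realized
coefficient–fitness covariances by roughly 10% at the default settings
(mean fitness is only ~1.4 SD above zero); the truth record therefore
reports both the configured covariances and the realized covariances with
final fitness, plus the flooring fraction, so tests can separate estimator
error from generator attenuation.  Covariate values are generated
independently of the coefficients (the model conditions on the covariate); a
dependence knob exists for robustness experiments but is off by default.
Passing recovery tests on these data shows the estimator is correct under
the model's assumptions, not that real field data satisfy them (territory
effects, covariate–coefficient dependence and non-Gaussian fitness remain
the user's responsibility to consider).

## Problem sizes and numerical choices in the test battery

Simulation-based checks use 50 replicates of the owl-sized generator for
parameter recovery and coverage, 50 replicates at 200 individuals / 15
years (order 1) for the null rejection rate of the selection LRT, and 50
replicates at 150 individuals / 15 years for order-selection behavior under
a true order of 0 — sizes chosen to keep the full battery at desk scale
while preserving the study's unbalanced structure.  Replicated fits use a
single moment-based optimizer start and reuse each replicate's univariate
optimum as the joint fit's starting point; spot checks show the same optima
as the 3-start default on these well-conditioned simulated datasets.
Smaller fixtures (60 individuals, 10 years) back the unit tests; the dense
REML oracle is only ever evaluated at n ≤ ~35.

## Known limitations

- Gaussian likelihood for a bounded count-like response and for relative
  fitness, following standard practice for this model class.
- REML LRT df convention is conservative at variance boundaries (see above).
- No pedigree/animal-model partitioning of the coefficient covariance into
  additive-genetic and permanent-environment parts; the among-individual
  variances here confound the two.
- SEs of variance components are asymptotic (observed information);
  coverage was verified by simulation at the owl-like size, but boundary
  fits report no SEs rather than misleading ones.
- The order-selection rule is the stepwise-LRT convention; it is not a
  consistent model-selection procedure and can stop early if an
  intermediate order adds little.
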