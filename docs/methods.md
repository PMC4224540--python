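# Methods

`growmort` implements a size-standardized analysis of the cross-species
trade-off between growth and mortality in cohorts of planted tree seedlings,
together with a synthetic-data generator that emulates the multi-census
field design such analyses are run on.

## Growth model

Basal diameter M (mm) of an individual follows the power-law growth ODE

    dM/dt = alpha * M^beta,

with alpha a growth coefficient (mm mm^-1 day^-1) and beta a dimensionless
scaling exponent shared across species. beta = 0 is constant linear growth,
beta = 1 exponential growth; for beta != 1 the ODE has the closed form

    M(t) = (M0^(1-beta) + alpha (1-beta) t)^(1/(1-beta)),

and `predict_size` switches to M0*exp(alpha t) within 1e-9 of beta = 1 (the
two branches agree to better than 1e-4 relative within 1e-6 of the switch).
Because conventional RGR comparisons confound intrinsic rate differences
with size differences, species are compared by the size-specific relative
growth rate at a common reference size M_c:

    SGR = alpha * M_c^(beta-1),

reported per year (x 365). With a shared beta, species rankings of SGR are
independent of M_c; the default reference is M_c = 10 mm at 4.5 % canopy
openness.

### Mixed-effects estimation

The observation model is y_ij = M(t_ij; alpha_i, beta_i, m0_i) + e_ij with
per-species residual SDs (the raw-diameter residuals are strongly
heteroscedastic across species) and individual-level parameters

    alpha_i = a_species + gamma * log(openness_i) + b1_i
    beta_i  = beta0 + b2_i
    m0_i    = mu0 + b3_i,

where (b1, b2, b3) are independent zero-mean Gaussian individual random
effects (a diagonal covariance; the generator's truth is diagonal and the
classical analogue is a pdDiag structure). The light covariate is the
openness average over censuses at which the sapling's height was <= 160 cm,
held constant afterwards — above that height a densiometer reads the light
the sapling creates, not what it experiences. When no reading below the
threshold exists the earliest reading is used. Individuals with fewer than
three diameter measures are excluded from growth fitting but retained for
mortality.

Fitting alternates, in the style of Lindstrom & Bates:

1. **PNLS** — at fixed variance parameters, Gauss-Newton on the penalized
   nonlinear least-squares criterion jointly in the fixed effects and all
   individual random effects. Block elimination reduces each step to one
   p x p solve plus an independent 3 x 3 solve per individual, so the step
   is fully vectorized.
2. **LME** — the model is linearized about the current estimates and the
   resulting linear mixed-model likelihood (ML or REML; residual scale and
   GLS fixed effects profiled out) is maximized over the relative
   random-effect SDs and per-species residual SD ratios.

Internally time is measured in units of 1000 days so that alpha-type
parameters are O(1); outputs are converted back to per-day units. Starting
values: a two-point finite-difference estimate of alpha per individual
(species medians), beta = 0.8, M0 = mean first-census diameter. The outer
loop stops when the approximate log-likelihood changes by < 1e-7 (relative)
or after 40 iterations. The reported log-likelihood is the
linear-approximation value at convergence — the same quantity classical
NLME software reports — and BIC is always built from its ML variant
(k = fixed effects + 3 RE SDs + residual parameters). A test verifies that
R's `nlme`, started at this package's solution on a small dataset, stays at
the same optimum with the same log-likelihood.

### Laplace polish (`refine=True`)

The alternating scheme's criterion uses a Gauss-Newton (Fisher)
approximation of the inner Hessian. On clean simulated data this leaves a
small O(sigma^2) upward bias in beta (~+0.005 at the default design) that
exceeds the Wald SE (~0.002), so nominal CIs undercover. Passing
`refine=True` re-optimizes a second-order Laplace marginal likelihood whose
inner Hessian keeps the residual-weighted curvature of the model function
(d2f/db2 obtained by central differences of the analytic Jacobian). In
replicate simulations at the default design this removes the bias (mean
bias ~2e-4) and restores nominal CI coverage. The polish roughly quadruples
the fit time, so it is off by default and enabled where bias matters
(recovery studies, the acceptance script). BIC comparisons must not mix
refined and unrefined fits.

Pseudo-R^2 is the squared Pearson correlation between observed diameters
and conditional (random-effects-included) fitted values; the marginal
variant (random effects at zero) is also reported. Trajectory confidence
bands draw fixed-effect vectors from N(theta_hat, vcov) and report per-time
2.5/97.5 percentiles of the implied curves.

## Mortality model

Survival is census-based: a death is only known to fall within an interval.
With constant hazard within an interval of length dt years, the interval
death probability is 1 - exp(-exp(eta + log dt)) — a binomial GLM with
complementary log-log link and offset log(dt), which puts coefficients on an
annual-hazard scale and makes probabilities compose exactly across
sub-intervals. Fixed effects: species intercepts, canopy openness (per %,
untransformed; a log option exists), and initial diameter (the first
recorded diameter, per mm). Random intercepts for individual and for census
occasion are crossed and integrated out by a Laplace approximation: the
inner mode is found by Fisher scoring, where both random-intercept blocks of
the penalized information are diagonal and a small Schur complement handles
the crossing. The outer optimization (L-BFGS-B over fixed effects and two
log-SDs) treats the marginal likelihood as a pure function of the
parameters — the inner solve restarts from zero each evaluation, because
warm-start hysteresis otherwise breaks the line search. With variances at
zero and one species the fit reproduces an ordinary cloglog GLM
(statsmodels is the oracle for that case in the tests). A species with no
observed deaths has no finite intercept; the optimizer's box bound then acts
as a boundary estimate and the fit carries a warning. Annual mortality
predictions set random effects to zero and dt = 1 year.

The mortality covariate default is the same averaged-canopy value used for
growth; per-census readings can be attached instead. The offset uses years;
using days would only shift species intercepts by log(365).

## Trait means and trade-off statistics

Species trait means pooled across experiments are estimated by a Gaussian
random-intercept model (species + experiment), fit by profiled ML with
Woodbury identities; a species estimate is the grand mean plus its BLUP
(a shrunken mean). Balanced experiment offsets cancel exactly; unbalanced
designs are where shrinkage lowers RMSE relative to raw averages.

Trait-demography association uses (a) a Pearson correlation matrix with
two-sided t tests on n-2 df, pairwise-complete cases, and no
multiple-testing adjustment by default (a Holm option exists); and (b)
standardized major axis regression, appropriate when both axes carry error:
slope = sign(r) sd(y)/sd(x), line through the centroid, significance from
the correlation test, and the standard likelihood-based slope interval
B = F(0.95; 1, n-2)(1-r^2)/(n-2), CI = slope(sqrt(B+1) +/- sqrt(B)). The
trade-off summary fits the SMA of annual mortality probability on SGR
(both at the 10-mm, 4.5 %-openness reference) and reports the implied
change in annual mortality, in percentage points, per +0.1 yr^-1 SGR
(slope x 0.1 x 100). The mortality axis is the annual probability at the
reference, not the cloglog intercept (an option allows the latter).

## Synthetic-data generator

The generator emulates an enrichment-planting census study: by default 15
species x 68 individuals, censused at 576, 815, 1166, 1474, 2885 and 3214
days after planting (the motivating design's final two assessments fell at
essentially the same day, so six distinct occasions are simulated), canopy
openness log-uniform on 0.5-26 % and static per individual (a jitter option
exercises the averaging rule), initial diameters ~N(4.12, 0.9^2) mm
truncated at 1 mm, height a deterministic allometry 10 * d^1.2 cm used only
to drive the 160-cm rule.

Species-level truth is drawn jointly: (log alpha, mortality intercept,
wood-density axis) come from a trivariate Gaussian whose correlations are
the configured targets (trade-off 0.54, wood density -0.74 with the growth
axis and -0.52 with the mortality axis), so the cross-species structure the
analysis estimates is present by construction. Species alpha intercepts
(lognormal, median ~6.2e-4, spanning roughly 4.3e-4-9.1e-4 mm mm^-1 day^-1
at 1 % openness) carry an additive light effect of 0.092/365 per log-%
openness — the annual-scale slope 0.092 is only dimensionally consistent
with alpha per year, and anchoring intercepts at log(openness) = 0 keeps
alpha positive across the full light range. beta = 0.86 common, individual
random-effect SDs (6.5e-5 day^-1, 0.02, 0.9 mm), per-species measurement
SDs log-uniform on 0.15-0.45 mm (a realistic caliper/field error; the
resulting conditional pseudo-R^2 ~0.999 exceeds the ~0.986 typical of field
data because the generator contains no model misspecification). Mortality
intercepts on the annual cloglog scale (mean -2.25, SD 0.37, i.e. annual
rates ~0.05-0.18 at the 4.5 %/4.12 mm reference) with slopes -0.11 per %
openness and -0.01 per mm initial diameter; deaths are drawn per census
interval and individuals are truncated after the census at which death is
first recorded, with the death census carrying alive = 0 and no diameter.
SLA, seed mass and leaf C:N are generated independent of demography. The
raw trait-observation generator adds experiment offsets and residual noise
around species means, optionally unbalanced.

What the generator does not emulate: spatial structure, temporal hazard
variation (the census-occasion variance truth is zero), ontogenetic shifts
in light response, real measurement-protocol artifacts, and the
model-misspecification component of real field data. Passing recovery tests
therefore certify the estimators under a correctly specified model, not
robustness to misspecification.

## Numerical choices and degenerate inputs

- Estimation guards: alpha floor 1e-8 (internal scale), M0 floor 0.1 mm,
  solution base clipped positive; line searches reject non-finite trial
  objectives.
- beta is estimated unconstrained (the data keep it well inside (0, 1));
  the Wald CI therefore needs no transformation.
- Zero-variance/zero-noise inputs degenerate gracefully: the growth fit
  recovers truth to optimizer tolerance; the trait model collapses to
  arithmetic means; the mortality fit reduces to the fixed-effects GLM.
- compare_bic enforces a shared data fingerprint and applies the 2-point
  rule: the simplest model within 2 BIC points of the minimum is preferred.

## Problem sizes in the test suite

Simulation-based tests run at desk scale, chosen as the smallest designs
that make the checks informative: growth-recovery replicates use the full
default design (15 x 68, 10 replicates, Laplace polish); mortality recovery
uses 6 replicates; BIC model-selection suites use 8-species populations
(20-40 individuals per species, 10 replicates each); unit-level fits use
4-6 species. The acceptance script runs the complete pipeline once at the
full default design.

## Known limitations

- The growth random-effect covariance is diagonal; correlated individual
  effects (e.g. alpha with M0) are not estimated.
- The unrefined alternating fit shares the small beta bias of classical
  first-order NLME linearization; use `refine=True` where it matters.
- The mortality Laplace approximation can inflate the individual-level
  variance on sparse binary data (few intervals per individual); species
  probabilities and slopes recover well, but the variance components are
  reported as approximate.
- SMA slope CIs use the standard r/n-based interval; no small-sample
  correction beyond it.
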