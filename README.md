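# growmort

Size-standardized growth–mortality trade-off analysis for seedling
demography.

## The problem

Comparing growth rates across tree species from field censuses is
confounded by size: relative growth rate (RGR) declines as plants grow, so
species measured at different sizes look intrinsically different even when
they are not. `growmort` implements the size-standardized workflow used in
multi-census enrichment-planting studies of shade-tolerant tropical tree
seedlings, for ecologists who want to (re-)run that analysis on their own
census data or study its statistical behaviour on simulated data:

1. **Growth.** Basal diameter follows the power-law ODE
   dM/dt = α·M^β (α in mm mm⁻¹ day⁻¹, β dimensionless), whose analytic
   solution M(t) = (M₀^(1−β) + α(1−β)t)^(1/(1−β)) is fitted to repeated
   diameter measurements as a nonlinear mixed-effects model: species
   intercepts and a log-canopy-openness slope on α, common β and M₀,
   individual random effects on all three parameters, per-species residual
   variances, ML/REML, BIC model comparison, and an optional second-order
   Laplace polish that removes the small β bias of first-order NLME
   linearization. Species are then compared by the size-specific relative
   growth rate at a common reference size, SGR = α·M_c^(β−1) (per year,
   default M_c = 10 mm).
2. **Mortality.** Census-interval survival is modelled as a binomial GLMM
   with complementary log-log link and log-interval offset
   (p = 1 − exp(−exp(η + log Δt))), which puts species intercepts, a canopy
   openness slope and an initial-diameter slope on an annual hazard scale,
   with crossed random intercepts for individual and census occasion.
3. **Trade-off.** Species trait means (wood density, SLA, seed mass, leaf
   C:N) are estimated by random-intercept pooling across experiments;
   trait–demography association is summarized by a Pearson correlation
   matrix and standardized major axis (SMA) regression, including the SMA
   of annual mortality on SGR — the growth–mortality trade-off — reported
   as percentage points of annual mortality per +0.1 yr⁻¹ SGR.

A synthetic-data module generates census, survival and trait tables with
the full statistical structure above (including a latent wood-density axis
linking growth and mortality across species), so every stage is testable
without any field data. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import growmort as gm
from growmort.mortality import build_intervals
from growmort.pipeline import attach_averaged_canopy
from growmort.tradeoff import species_demography, tradeoff_summary

census, traits, truth = gm.generate_population(gm.SimConfig(seed=4))
growth = gm.fit_growth_nlme(census, refine=True)
lo, hi = growth.beta_ci()
print(f"beta = {growth.beta:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
      f"pseudo-R2 = {growth.pseudo_r2:.3f}")
print(f"alpha range: {growth.alpha_by_species.min():.6f}-"
      f"{growth.alpha_by_species.max():.6f} mm mm^-1 day^-1")
print(f"light slope: {growth.light_slope * 365:.3f} yr^-1 per log-% openness")

intervals = attach_averaged_canopy(census, build_intervals(census))
mort = gm.fit_mortality_glmm(intervals)
print(f"mortality light slope: {mort.light_slope:.3f} per % openness")

demog = species_demography(growth, mort)   # SGR & annual mortality @ 10 mm
print(tradeoff_summary(demog))
```

prints

```
beta = 0.861 (95% CI 0.858-0.863), pseudo-R2 = 1.000
alpha range: 0.000428-0.000970 mm mm^-1 day^-1
light slope: 0.093 yr^-1 per log-% openness
mortality light slope: -0.124 per % openness
SMA slope 1.033 (r=0.86, R2=0.74, p=4.35e-05, n=15); +0.1 yr^-1 SGR -> 10.3 percentage-point increase in annual mortality
```

Reading this: the common scaling exponent β ≈ 0.86 says growth decelerates
with size (between linear β=0 and exponential β=1); the fitted species
growth coefficients span the configured range; growth rises and mortality
falls with canopy openness; and across species, faster-growing species die
more — the positive SMA slope quantifies the trade-off at the common 10-mm
reference size, unconfounded by species size differences.

The same stages are available from a shell:

```bash
growmort simulate --seed 1 --out run/
growmort fit-growth --census run/census.csv --ref-size 10 --method reml --out run/
growmort fit-mortality --census run/census.csv --out run/
growmort report --seed 1 --out run/    # full pipeline + manifest.json
```

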