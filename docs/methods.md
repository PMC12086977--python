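# Methods

## The decay model and its estimator

Litter mass loss is modelled as single-pool exponential decay,
ln *M*ₜ = ln *M*₀ − *k t*, with *M*ₜ the percent of initial mass remaining
(0–100 scale, so the intercept sits near ln 100 ≈ 4.605), *t* the
incubation period in years, and *k* the decay constant (year⁻¹).  The
three design removal days enter as the fixed fractions 0.0822, 0.1644 and
0.2466 of a 365-day year.  Slopes are stored with a negative sign for mass
loss; magnitude accessors serve ratio arithmetic.

`fit_multigroup` extends the linearized model to the full factorial: one
shared intercept (a single column of ones) and one slope column per
treatment cell, equal to *t* for that cell's bags and 0 elsewhere, in the
canonical cell order (proliferation Yes→No, exclusion Yes→No, species
maple→beech→mixed).  Estimation is ordinary least squares with t-based
95% intervals.  With flat priors these intervals coincide numerically with
Bayesian credible intervals, which is why OLS is the sole estimator
offered.  A cell observed at fewer than two distinct time points makes the
design unidentifiable and raises an error naming the cell.  Plot-level
covariates, when supplied, are joined per record and estimated jointly.
Physiological time can replace calendar time: cumulative growing
degree-days, with a daily contribution max(0, daily-mean − base) at base
5 °C.  Daily means (not sub-daily positive parts) define the contribution;
days with logging gaps over 1.5× the median interval are dropped with a
warning.  At constant temperature the GDD axis is proportional to the
calendar axis, so slopes rescale by an exact constant — a property the
tests exploit.

The per-bag *instantaneous k*, (ln remaining% − ln 100)/year-fraction, is
the closed-form single-observation estimator; it anchors the mixed-bag
per-species rates (component masses referenced to their 1.5 g initial
aliquots) and the rank analyses.

## Additivity testing

The additive expectation for a 50:50 mixture is the arithmetic mean of the
monospecific rates; its variance, for independent estimates, is
(var₁ + var₂)/4.  The test statistic is
z = (observed − expected)/√(var_obs + var_exp), two-sided against 1.96 by
default (configurable); z² is exposed for comparison with pooled-variance
formulations stated as squared differences over pooled variances.  The
verdict distinguishes synergism (observed magnitude above expected) from
antagonism once |z| reaches the critical value.  Two caveats are
documented rather than hidden: (a) the z assumes independent observed and
expected estimates — slopes taken from a single shared-intercept fit are
positively correlated, making the test mildly conservative in that use;
(b) with estimated variances the statistic is t-like, so its finite-sample
type-I error runs one-to-two points above the nominal 5% at the study's
cell sizes.  The null-simulation experiment therefore estimates each
cell's rate from its own (disjoint) bags, matching the independence
assumption.

## Rank statistics and environmental tests

Kendall's *W* uses mid-ranks within blocks and the standard tie
correction by default (W = 12S/(m²(n³−n) − mΣT), χ² = m(n−1)W on n−1 df);
ranking direction gives rank 1 to the fastest decay and is configurable.
Spearman's ρ is the Pearson correlation of mid-ranks.  The permutation
group test is a one-way PERMANOVA on Euclidean distances: the pseudo-F
from the sum-of-squares partition (identical to the classical one-way F
in the univariate case), a seeded label-permutation null, and the add-one
p-value (hits + 1)/(permutations + 1).  The published two-way contrasts
are approximated one-way with the other factor's levels pooled; the
two-way interaction terms were all null in the field data, so the one-way
tests carry the findings.  Compositional (texture) data are brought into
Euclidean space by the centered log-ratio transform, with no
zero-replacement: zero parts are an error.

Group summaries use sample (n−1) standard deviations throughout — the
convention under which the published plot-table summaries reproduce — and
CV% = 100·SD/mean.

## The synthetic generator

The generator is built to be the exact inverse of the estimator: percent
remaining is exp(ln 100 − k·t·meshmod + ε) with ε mean-zero noise of
standard deviation `ln_noise_sd` (default 0.1) on the ln scale, i.e.
multiplicative on mass.  Because a bag cannot gain mass, ε must be bounded
above by k·t; a one-sided truncation of a normal would shift its mean and
bias every slope (and, through the shared intercept, the other cells'
slopes too).  ε is therefore drawn as k·t − Gamma(mean = k·t, sd = σ): a
mean-zero, constant-variance distribution supported on (−∞, k·t], which
converges to Normal(0, σ) whenever the expected loss k·t is large against
σ and skews left near the no-loss boundary — masses hug 100% with
occasional larger losses, which is also what early-stage field data look
like.  Constant variance across cells keeps the pooled-residual OLS
intervals honest: measured coverage of the true slopes is 0.94–0.97 per
cell at 1000 replications.

Mixed bags draw each species' remaining mass independently from its own
rate (the mixed cell's rate unless per-species rates are configured) and
sum them.  Each component carries √2 × the configured ln-noise so the
summed bag mass again has ln-scale noise ≈ `ln_noise_sd`, preserving
homoscedasticity across all 648 bags.  Component masses sum to the bag
total exactly by construction; the reader enforces the sum within 0.005 g
(two analytical-balance readings) for external data.

Default design constants are the field campaign's: 3 + 3 sites (labels
1–3 with beech-sapling understories, 5–7 beech-free), paired
excluder/rainfall plots per site, 3 species × 3 mesh × 2 replicates × 3
removal days = 648 bags, with site 3 dropped by default (540 bags)
mirroring the samples lost in the field.  True rates default to the
published slope magnitudes; under exclusion only pooled monospecific
slopes were published (−0.248 maple, −0.307 beech), so both proliferation
levels share them and the mixed excluder cell takes their midpoint
(−0.2775).  Mesh modifiers default to 1 (the field result found no
consistent mesh ordering).

Moisture grids are 6 × 7 = 42 nodes per plot, each node the mean of 3
lognormal readings.  The node-level mean and CV% match the configured
exclusion level (defaults: 15.57%/24.40% rainfall, 8.82%/54.10% excluder,
the published group summaries), so the per-reading CV is inflated by √3;
CV = 0 degenerates to the exact mean.  Temperature logs superimpose a
sinusoidal diurnal cycle whose within-day samples sum to zero exactly, so
daily means equal the configured profile.  One global seed drives
deterministic per-stage substreams.

What the generator does **not** emulate: site- or plot-level random
effects (replicates were absorbed into the error term in the field
analysis, and no variance component was published to calibrate one),
month-to-month weather variation in k, faunal mesh effects, and
multi-pool (double-exponential/Weibull) kinetics.  Passing tests therefore
validate the estimation chain under the fitted model's own assumptions,
not the field realism of that model.

## Problem sizes for the simulation experiments

Interval coverage uses 200 replications of the 540-bag design; the
additivity null uses 250 replications × 4 strata = 1000 z-tests on the
full 648-bag design; the permutation-test level uses 1000 null datasets of
16 × 2 observations at 99 permutations each, where the add-one p-value's
rejection probability at α = 0.05 is exactly 5%.  These sizes put Monte
Carlo error well inside the asserted bands while keeping the whole suite
quick to run.

## Numerical conventions and edge cases

Percentages are carried on the 0–100 scale unrounded; rounding (3 decimals
for rates, 1 for percentages) happens only at presentation.  ln is the
natural logarithm.  Intervals are closed for containment checks.  Total
litter disappearance (0% remaining) is outside the model and is an error,
as are mass gains above the initial aliquot in external data.  A fully
tied concordance table has an undefined tie-corrected denominator and is
reported as W = 1 (no information against agreement).  Perfectly
homogeneous groups give an infinite pseudo-F when separated and 0 when
identical.  CSVs round-trip floats losslessly (17 significant digits out,
round-trip parsing in).  Missing data are absent rows, never sentinels.
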