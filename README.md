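# litterdecay

Analysis pipeline for litterbag decomposition experiments under a
rainfall-exclusion factorial design, built around a field study in
sugar-maple stands of the Kenauk Reserve (Quebec): paired drought
(rainfall-excluder) and rainfall-accessible plots, with and without dense
American-beech sapling understories, holding mesh bags of maple litter,
beech litter, or their 50:50 mixture that are retrieved at 30, 60 and 90
days.

The package answers three questions ecologists ask of such designs:

1. **How fast does litter decay, per treatment?**  Mass loss follows the
   single-pool Olson model *M*<sub>t</sub> = *M*<sub>0</sub>·e<sup>−kt</sup>,
   linearized as ln *M*<sub>t</sub> = ln *M*<sub>0</sub> − *kt* and extended
   to one shared intercept plus 12 slope coefficients (year⁻¹), one per
   Proliferation × Exclusion × Species cell, estimated by OLS with t-based
   95% intervals.  A per-bag *instantaneous k* =
   (ln remaining% − ln 100%)/year-fraction and a growing-degree-day
   (base 5 °C) time axis are also provided.
2. **Do mixtures decay additively?**  Additivity means the mixed-bag rate
   equals the mean of the two monospecific rates.  The package computes
   expected rates, standardized differences ([observed − expected]/expected),
   a variance-propagated z-test, per-species rates inside mixed bags (from
   their 1.5 g component masses), and in-mixture vs monospecific speed
   ratios.
3. **Are rankings consistent, and what does the environment do?**
   Kendall's coefficient of concordance *W* (mid-ranks, tie-corrected)
   across removal dates and mesh sizes; Spearman correlations; soil-moisture
   grid summaries (mean, SD, CV%); basal-area-weighted shade tolerance;
   centered log-ratio texture transforms; and one-way Euclidean PERMANOVA
   with seeded permutations.

A synthetic-data generator emulates the full 648-bag design (including the
loss of one site, as happened in the field) with multiplicative noise
around the exponential decay, so the whole chain is testable end to end;
the study's published plot tables and slope coefficients are bundled in
`litterdecay.study` for the arithmetic that reproduces exactly.

## Worked example

```python
from litterdecay import (default_study_config, generate_bags, fit_multigroup,
                         expected_mixture_k, standardized_difference)

records = generate_bags(default_study_config(seed=1))   # 540 bags, 5 sites
fit = fit_multigroup(records)
print(len(records), round(fit.intercept, 3))
# 540 4.601        <- intercept ~ ln(100) = 4.605: ~100% mass at day 0

# additivity arithmetic on the published rainfall-accessible slopes
print(round(expected_mixture_k(-1.026, -0.787), 3))     # -0.907
print(round(100 * standardized_difference(-1.026, -0.812)))  # 26
```

The fitted slopes are the per-cell decay rates (negative = mass loss); for
the seed shown, the mean rainfall-accessible slope is −0.778 year⁻¹
against −0.303 year⁻¹ under the excluders — the simulated drought slows
early decay roughly 2.6-fold, the pattern the design was built to detect.
The `-0.907` is the rate the 50:50 mixture *should* show under beech
saplings if mixing has no effect, and `26` is the percent speed-up of
maple decay under a beech-sapling understory relative to beech-free plots.

Command-line equivalents: `litterdecay simulate/fit/additivity/concordance/
envsummary/run-all`, and the numbered drivers under `analysis/`
(`01_simulate.py` … `05_environment.py`) run the same stages as a
narrative, writing tables under `results/`.

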