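# lythrum

Inbreeding-depression analysis for multi-season common-garden experiments,
modelled on a four-year study of purple loosestrife (*Lythrum salicaria*)
comparing self-fertilised (S) and cross-fertilised (X) progeny from 29
maternal families, with and without intraspecific competitors, over one
glasshouse season and three field seasons.

The package is aimed at plant evolutionary ecologists who want the whole
chain — experiment structure, life-history trait analysis, growth-curve
modelling, and lifetime-fitness estimation — as seeded, reproducible code.
Because the original field data are not publicly archived, a calibrated
synthetic-data generator stands in for them, and every estimator is tested
end-to-end against the study's reported effect sizes.

## What it computes

**Inbreeding depression (δ).** The symmetric relative-performance index

δ = 1 − *w<sub>s</sub>*/*w<sub>o</sub>* if *w<sub>o</sub>* > *w<sub>s</sub>*,  δ = *w<sub>o</sub>*/*w<sub>s</sub>* − 1 if *w<sub>s</sub>* > *w<sub>o</sub>*

bounded in [−1, 1], with family-bootstrap 95% CIs and family/block-stratified
permutation tests in place of mixed-model χ² inference. The same index over
competition environments gives competitive relative performance (RP).

**Growth.** Four asymptotic height models — monomolecular, logistic
*y* = Asymp/(1 + e^{(xmid−t)/scal}), Gompertz *y* = Asymp·e^{−b2·b3^t},
and four-part logistic — fitted per plant and aggregated (a two-stage
stand-in for nonlinear mixed effects), compared by small-sample-corrected
AIC, with Monte-Carlo 95% bands for average growth rate
AGR(t) = dy/dt and time-resolved δ(AGR)(t) significance windows on
days 0–150.

**Lifetime fitness.** Per-season multiplicative fitness
(germination × survival × flowering × mean inflorescence mass) summed into
cumulative reproductive success, estimated two ways: per-family δ averaged
over families (mean of ratios), and a 246-seed × 5000-run resampling
simulation from the observed per-treatment distributions with mortality
carry-forward (ratio of means).

## Worked example

```python
from lythrum import (DesignConfig, generate_experiment, family_cumulative,
                     resampling_fitness, ResamplingConfig, fit_growth_model,
                     relative_performance)

ds = generate_experiment(DesignConfig(rng_seed=7))

fam = family_cumulative(ds, n_boot=2000, seed=7)
for year, rp in fam.delta_by_year.items():
    print(f"family delta {year}: {rp.estimate:+.2f} "
          f"(95% CI {rp.ci_low:+.2f}, {rp.ci_high:+.2f})")

res = resampling_fitness(ds, ResamplingConfig(n_seeds=246, n_runs=5000, rng_seed=7))
rp = res.delta_by_year["cumulative"]
print(f"resampling cumulative delta: {rp.estimate:+.2f} "
      f"(95% CI {rp.ci_low:+.2f}, {rp.ci_high:+.2f})")

fit = fit_growth_model(ds.heights.query("year == 2014"), "gompertz",
                       covariate_structure="breeding", plants=ds.plants)
gp = fit.group_params.set_index("level")["estimate"]
print(f"2014 Gompertz asymptote: {fit.params['Asymp']:.1f} cm "
      f"(selfed {gp['selfed']:.1f}, outcrossed {gp['outcrossed']:.1f}, "
      f"delta {relative_performance(gp['selfed'], gp['outcrossed']):.2f})")
```

prints

```
family delta 2014: +0.56 (95% CI +0.44, +0.67)
family delta 2015: -0.12 (95% CI -0.38, +0.15)
family delta 2016: +0.51 (95% CI +0.27, +0.73)
family delta 2017: +0.41 (95% CI +0.20, +0.61)
family delta cumulative: +0.58 (95% CI +0.45, +0.68)
resampling cumulative delta: +0.65 (95% CI +0.56, +0.71)
2014 Gompertz asymptote: 124.3 cm (selfed 112.8, outcrossed 135.5, delta 0.17)
```

Read it as: selfed offspring suffered a ~56% fitness disadvantage in the
glasshouse season, none in the transition year to the field (the CI spans
zero), and a ~40–50% disadvantage in the later field seasons; cumulatively
over four seasons the two estimators put δ at 0.58 (family-based) and 0.65
(resampling). Outcrossed plants also reach an 18–20% taller asymptote in
the first season (δ(Asymp) = 0.17).

## Command-line pipeline

```sh
lythrum all --seed 1 --out results/
```

runs simulate → endpoints → growth → agr → multiplicative, writing tidy
CSVs (`summaries.csv`, `tests.csv`, `aic_table.csv`, `fits.csv`,
`agr_bands.csv`, `windows.csv`, `family_fitness.csv`, `delta_report.csv`)
plus a JSON manifest per stage (config echo, seed, checksums) so every
artifact is regenerable from the manifest alone. Individual stages accept
`--data` (a dataset directory from `simulate`), `--config` (flat YAML
key-values), and `--n-boot/--n-perm/--n-sim` overrides.

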