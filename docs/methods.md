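# Methods

`lythrum` re-implements, as a tested and reusable pipeline, the statistical
analysis of a four-season common-garden experiment comparing self- and
cross-fertilised progeny of purple loosestrife (*Lythrum salicaria*). The
raw field data are not publicly archived, so the pipeline ships a
synthetic-data generator calibrated to the experiment's design and reported
effect sizes; every estimator is exercised end-to-end on generated data.

## The relative-performance index

Inbreeding depression is expressed with the symmetric relative-performance
index. For selfed performance *w<sub>s</sub>* and outcrossed performance
*w<sub>o</sub>*:

- δ = 1 − *w<sub>s</sub>*/*w<sub>o</sub>* when *w<sub>o</sub>* > *w<sub>s</sub>*,
- δ = *w<sub>o</sub>*/*w<sub>s</sub>* − 1 when *w<sub>s</sub>* > *w<sub>o</sub>* (negative, symmetric),
- δ = 0 on a tie.

The index is bounded in [−1, 1], antisymmetric and scale-invariant; these
are enforced as property tests. When exactly one group has zero
performance the index saturates at ±1 (continuity of the bounded
statistic); when both are zero it is 0 with a warning. The same index
across competition environments (no competitor / selfed competitor /
outcrossed competitor) gives the competitive RP family, signed so that the
less-competed group plays the "outcrossed" role.

Interval estimates are 2.5/97.5 percentile bootstrap intervals resampling
maternal families with replacement (2000 resamples by default). The
original mixed-model/χ² inference is not fully recoverable from its
description, so hypothesis tests are permutation tests that respect the
design's exchangeability: breeding labels permute within family, competition
labels across pots within spatial block, and the interaction permutes
breeding within family × competition strata, with
p = (1 + #{|stat*| ≥ |stat|}) / (1 + n_perm). No multiple-testing
correction is applied, matching the original analysis.

## Synthetic experiment generator

Design defaults: 29 maternal families; 10 selfed + 10 outcrossed seeds per
family in the germination trial; 3 selfed and 3 outcrossed germinants per
family become focal plants across six treatments (S, X, SS, SX, XS, XX);
six spatial blocks; competitors drawn from other families' surplus
germinants; one glasshouse season (2014) followed by three field seasons.

Fates are drawn hierarchically. Each family has a shared normal random
effect (SD 0.5) acting on the logit of germination, seedling survival,
annual survival and flowering, and (scaled by 0.3) on log mass.
Days-to-germination is Poisson (mean 8). Inflorescence mass conditional on
flowering is log-normal with CV 0.6. Mortality carries forward: a plant's
death year carries its last record and later years have none. Two-plant
pots face an annual discard probability in the field (0.03, 0.03, 0.05),
emulating the removal of plants that became indistinguishable from their
pot mate; both plants leave the risk set together. Heights follow the
season's growth curve with a per-plant log-normal asymptote multiplier
(CV 0.15) and Gaussian residuals (SD 5 cm), measured on 8 occasions in the
glasshouse season and 4 in the field seasons, with per-plant measurement
dates jittered a few days around each nominal occasion (field crews visit
over several days; dates are standardised to days since May 11). The
season-2 cohort is small in stature, so no competition or breeding effects
are placed on the 2017 height schedule — no growth model is fitted to the
fourth season at all (too few occasions), matching the original analysis.

Calibration. The germination ratio is 0.88 (δ_germ = 0.12). Growth-curve
constants are the reported fits: season 1 Gompertz (Asymp 121.69, b2 4.28,
b3 0.97) with an 18% outcrossed asymptote advantage; seasons 2–3 logistic
(36.95/59.79/12.57 and 91.79/39.96/29.13) with 10% and 29% advantages.
Survival/flowering/mass contrasts were calibrated so that the
*family-based* yearly δ estimates centre on the reported 0.50 / ≈0 /
0.40 / 0.44. This required component contrasts stronger than the reported
marginal ratios: with only three offspring per family × treatment, the
family estimator is a mean of noisy ratios and attenuates markedly toward
zero (Jensen-type bias plus ±1 saturation in low-flowering seasons). The
outcrossed mass means (8.0 / 0.8 / 2.5 / 3.0 g) set the between-season
fitness weighting, with the glasshouse season contributing ~75% of
cumulative fitness. Competition environments have no effect under the
default calibration; `competition_mass_effect` can inject one for power
studies. `CalibrationParams.equalized()` produces the matched no-effect
(null) calibration used by the type-I checks.

What the generator does not emulate: spatial autocorrelation within
blocks, year-to-year weather correlation, pollinator behaviour, clonal
growth (the species has none), or trait–trait correlations beyond those
induced by the shared family effect and survival gating. Passing tests
therefore demonstrate correct estimator behaviour under the design's
sampling structure, not fidelity to any particular field dataset.

## Growth curves and fitting

Four asymptotic models are supported (monomolecular, logistic, Gompertz,
four-part logistic), each with closed-form first derivatives and analytic
Jacobians; the logistic forms use the numerically stable sigmoid
parameterisation. Time is days since May 11 within each season.

A full nonlinear mixed-effects fit is under-determined by the available
description, so the estimator is two-stage:

1. per-plant nonlinear least squares (bounded trust-region, data-driven
   starting values; constant series are excluded with a warning, and more
   than 50% stage-1 failures abort the model);
2. precision-weighted aggregation of the per-plant estimates. Weights are
   *design-based*: pooled residual variance × (JᵀJ)⁻¹ with the Jacobian
   evaluated at the population mean, so a plant's weight reflects its
   measurement design only. (Weights taken from each plant's own fitted
   curvature correlate with the estimate itself and bias the aggregate —
   observed as a ~6% downward asymptote bias in the 4-occasion seasons.)
   With a covariate structure, treatment-level means of the asymptote (and
   optionally other parameters) are aggregated per level, with family as
   the blocking factor in the reported standard errors. Levels with fewer
   than two converged plants drop their covariate (convergence fallback).

The empirical between-plant parameter covariance divided by the number of
plants stands in for the sampling covariance of the population mean; it
feeds the Monte-Carlo bands below.

Model comparison needs a likelihood that is comparable across families of
curves. A single population-curve likelihood cannot discriminate them
(between-plant asymptote variation dominates the residual), while a fully
free per-plant likelihood lets the four-parameter model interpolate
four-point seasons. The comparison likelihood therefore gives every plant
one free asymptote-like scale — profiled in closed form — with shape
parameters shared across plants (optimised by bounded least squares from
two starting points). This mirrors the per-plant random grouping of a
mixed model and gives all candidates identical per-plant flexibility;
k = n_plants + (p − 1) + 1. Because k is a sizeable fraction of n
(roughly one parameter per four observations), selection uses the
small-sample corrected criterion AICc; the table reports plain AIC
alongside. Ties break deterministically by registry order. Under the
default calibration the generating family is recovered in ≈100% (season-1
Gompertz) and ≈94% (season-3 logistic) of replicate cohorts.

## Average growth rate (AGR)

AGR is the closed-form derivative of the fitted curve (cm/day) on a grid
from day 0 to 150 in 0.05-day steps (the reporting resolution of the
original window endpoints). Parameter uncertainty is propagated with 1000
multivariate-normal draws per group from the fitted mean and the
covariance of the mean; draws outside the parameter domain are rejected
and redrawn (counts logged), and a non-PSD covariance is repaired to the
nearest PSD matrix. Pointwise 2.5/97.5 percentiles give the band.

δ(t) applies the relative-performance index to matched draw pairs
(draw i of one group with draw i of the other; pairing is the default and
is variance-reducing, an unpaired mode is available). Significance windows
are maximal grid runs where the pointwise CI excludes zero. Grid cells
where a drawn AGR is non-positive use the saturating zero rule and are
flagged. The two groups' draws must come from independent seeds (the CLI
shares one generator across groups); seeding both groups identically
collapses the paired CI to zero width. Under the null calibration the mean
total window length over seeded replicates is statistically consistent
with the nominal 5% of the grid (≈9 ± 3 days vs 7.5), and most null
datasets show no window at all.

## Multiplicative lifetime fitness

Seasonal fitness of a group is germination × proportion of the cohort
alive × proportion of survivors flowering × mean inflorescence mass of
flowering plants; germination is sampled once (2014) and multiplies every
season; cumulative reproductive success sums seasons. Survival enters as
cumulative cohort survival and flowering conditional on survival, so the
product equals expected per-seed output.

The family-based estimator computes per-family seasonal and cumulative
fitness per breeding treatment, δ within family (families with both
treatments at zero contribute 0, flagged), and averages over families —
a mean of ratios — with the SE over family means and a family-bootstrap
CI. Families missing one treatment entirely are excluded with a warning.

The resampling estimator forward-simulates 246 seeds per breeding
treatment for 5000 runs, drawing each component with replacement from the
observed per-treatment-per-year values (indicator pools are drawn as
Bernoulli at the pool mean, which is distributionally identical; masses
are resampled from the empirical pool), with mortality carry-forward.
"Cumulative output" is the summed inflorescence mass per simulated seed.
δ point estimates apply the index to across-run mean fitness — a ratio of
means — with CIs from the 2.5/97.5 percentiles of per-run δ. A season
whose risk pool is empty (no survivor to resample from) raises an error
naming the cell. The same machinery grouped by competition environment
yields the competitive RP set.

The two estimators agree exactly on deterministic components (tested) and
diverge under family-level noise: the mean of ratios is attenuated toward
zero relative to the ratio of means. Under the default calibration the
family-based cumulative δ centres on ≈0.50 and the resampling cumulative δ
on ≈0.58 — the same ordering, for the same reason, as the original
pair of estimates (0.48 vs 0.68).

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical CSV
output. Percentile (not BCa/normal) intervals are used throughout for
consistency. Heights are floored at 0 cm (a measured plant cannot have
negative height), which slightly inflates early-season means when the true
curve is within one residual SD of zero — visible as the four-part model
occasionally winning the low-stature first field season. Permutation
p-values have resolution 1/(1 + n_perm) with n_perm ≥ 999 enforced.
Degenerate inputs (constant series, empty treatment cells, all-zero
fitness) are flagged or excluded with named warnings rather than silently
dropped.

Simulation-based checks in the test suite use 20–50 seeded replicates per
claim and 1000 replicate experiments for the permutation type-I rate;
the acceptance script reports medians over 20 replicate experiments per
target. These sizes give Monte-Carlo standard errors comfortably inside
the tolerance of each check while keeping the default runs desk-scale.

## Known limitations

- The two-stage estimator is not an NLME fit; its standard errors treat
  per-plant estimates as data and are approximate for unbalanced designs.
- Pointwise (not simultaneous) AGR bands reproduce the original reading;
  total window length under the null is controlled in expectation per
  time-point, not family-wise.
- The resampling estimator pools plants across families within treatment,
  so it ignores family structure by construction (as described in the
  original method).
- The generator's calibration binds the family-based yearly δ values;
  single-trait marginal contrasts (e.g. the printed mass ratios) are then
  implied quantities and are reproduced only approximately.
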