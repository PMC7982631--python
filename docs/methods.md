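# Methods

## Inputs and canonical representation

The pipeline consumes burden tables in the GBD results-tool export dialect
(`measure_name, location_name, sex_name, age_name, year, metric_name, val,
upper, lower`), remappable through a dialect map. Age groups are the GBD
5-year bins "0 to 4" … "95 plus" plus the aggregates "All Ages" and
"Age-standardized"; the latter is accepted on read but dropped before any
ratio computation, because the ratio indices are defined on counts per age
group (or on summed all-age counts), not on standardized rates.

**Counts, not rates.** All downstream ratios are computed from count-metric
cells. Within a stratum a count ratio equals the corresponding rate ratio,
and published rates are rounded to two decimals, which breaks exact
arithmetic; counts reproduce published percent-change and decomposition
figures exactly. This is a deliberate canonical choice, configurable via the
`metric` argument of `pivot_panel`.

Strata missing any of the six measures are returned in an exclusion table
with a reason, never silently dropped, and no value is ever imputed for a
missing measure. The identity DALY = YLL + YLD is checked at pivot time with
a 0.1% relative threshold; violations warn rather than fail, since published
tables carry internal rounding (the 1990 global counts miss the identity by
about 1.5 × 10⁻⁶ relative).

## Secondary ratio indices

Per stratum: `mir = deaths/incidence`, `daly_prev = dalys/prevalence`,
`prev_inc = prevalence/incidence`, `yll_yld = ylls/ylds`. A zero denominator
marks the stratum invalid with the affected ratio(s) named; invalid strata
are excluded from model fitting but kept in outputs. Denominators are not
epsilon-padded: padding distorts exactly the small strata it is meant to
save, while flagged exclusion leaves an audit trail. A zero numerator over a
positive denominator is a legitimate 0. No ordering between the ratios (such
as `mir ≤ prev_inc`) is assumed or asserted.

## The QCI model

PCA is taken on the **correlation** matrix of the four indices — i.e. on
z-scored columns — because the ratios live on incommensurable scales (MIR
≪ 1 while prev/inc ≈ 8) and a covariance PCA would simply recover the
largest-variance column. Standardization uses the fitting-set mean and
sample standard deviation (ddof = 1). A column whose standard deviation is
indistinguishable from rounding noise on its own scale (≤ 1e-12 relative)
is treated as constant and rejected by name.

The loading vector is the leading eigenvector of the 4×4 correlation matrix
(`numpy.linalg.eigh`). Two sign conventions are applied in order:

1. deterministic sign fix — the largest-magnitude loading is made positive,
   so results do not depend on the eigensolver's arbitrary sign;
2. orientation — a factor in {−1, +1} chosen so the score is non-positively
   correlated with MIR over the fitting set (higher score = better care).

After orientation the MIR loading itself must be ≤ 0; if the data produce a
leading component in which mortality loads *with* the beneficial direction,
fitting fails loudly rather than deliver a score whose harm response is
inverted. Variance explained is the leading eigenvalue divided by 4.

**Rescaling.** Scores are mapped affinely to [0, 100] using the min and max
oriented score of the fitting set. Min–max is the simplest map attaining
both endpoints; it is a genuine modeling choice, and absolute score values
depend on it (a different 0–100 map yields different absolute scores with
the same ranking). Out-of-fit scores falling outside the fitting range are
clipped and flagged. Scoring a fitting-set vector reuses the identical
arithmetic path, so fit-time scores are reproduced bit for bit.

**One pooled model.** The model is fitted once on all finest-level strata
(location × year × sex × age group) over the whole study period. Coarser
scales are scored by summing the constituent measure counts, recomputing the
four ratios, and scoring with the same model — never by averaging
constituent QCIs, which would weight strata equally regardless of size and
break comparability across scales. Aggregation coverage is checked: a group
missing part of the summed-out grid raises rather than silently aggregating
a subset. The estimator follows the scikit-learn fit/transform contract
(`QualityOfCareIndex`), so it composes with sklearn pipelines; fitted state
serializes to a flat `key=value` text file with `repr`-precision floats for
an exact round trip.

## Gender disparity

GDR = QCI(female)/QCI(male) on the rescaled 0–100 scale, per (location,
year, age group). Raw first-component scores are affine with an arbitrary
zero, so their ratios are meaningless — the published definition is on QCI
and that is what is implemented. A male score of exactly 0 (the rescale
endpoint) yields an undefined ratio, flagged, rather than ±∞. Keys with only
one sex are excluded with the missing sex named. Because near-one ratios can
hide jointly low scores, `scatter_pairs` emits the paired absolute scores
for inspection; no statistical test is attached to GDR.

## Trend decomposition

Given reference-year age-specific rates, the reference age structure and the
current population, the two counterfactual expected counts are

```
e_growth       = (Σ_a pop_cur(a)) · Σ_a structure_ref(a) · rates_ref(a) / 1e5
e_growth_aging =  Σ_a pop_cur(a) · rates_ref(a) / 1e5
```

and the contributions, as percents of the reference count n_ref:
growth = (e_growth − n_ref), aging = (e_growth_aging − e_growth),
rates = (n_cur − e_growth_aging), each × 100/n_ref. The denominator n_ref
was fixed by verifying that it reproduces the published global rows from
their printed counts. Additivity (growth + aging + rates = overall) is
algebraic; the floating-point residual is measured relative to the
largest-magnitude term and stays near machine precision.

Within `decompose_panel`, rates are always derived as count/population from
the panel itself rather than read as pre-rounded rate rows, guaranteeing
numerator/denominator consistency; age resolution is fixed at the 5-year
bins. Groups missing any age bin in counts or populations for either year
are excluded with a reason.

Note that in the published SDI-quintile table the printed contribution
percentages are inconsistent with the printed counts of the same row (each
matches a *neighbouring* row's counts); only the three global rows are
arithmetically self-consistent, and only those are used as reference values
anywhere in this package.

## Synthetic data generator

The generator emulates the structural features of a GBD burden extract that
the method actually exploits, with a latent quality scalar q ∈ (0, 1) per
location (drawn uniformly on (0.05, 0.95)):

- case fatality: MIR(q) = m_max − (m_max − m_min)·q, default bounds
  (0.02, 0.5) — bracketing the observed global thyroid-cancer MIR ≈ 0.16;
- prevalent duration: prev/inc(q) = d_min + (d_max − d_min)·q, default
  (2, 12) years around the observed global ≈ 8.4;
- YLD = prevalence × disability weight (default 0.06); YLL = deaths ×
  remaining life expectancy at the age-bin midpoint (87.5-year horizon,
  floored at 3 years); DALY = YLL + YLD exactly.

Age-specific baseline incidence rises linearly to age 74 and then
geometrically (×1.6 per bin), mirroring the sharp ascent of thyroid-cancer
incidence after 75; the female rate is the male rate × 2.5 by default, so
the all-age female:male incidence ratio sits in the observed 2–3 band.
Population pyramids are discretized beta densities; the current year scales
totals by `pop_growth_factor` (default 1.6 over 1990→2017) and tilts the
pyramid older via `aging_shift` (default 0.15), giving the decomposition
genuine growth and aging signal with rates held constant by default.

**Noise model.** Independent multiplicative lognormal factors (median 1,
log-sd `noise_sd`, default 0.1) are applied per stratum to the three primary
quantities — incidence, the case-fatality link and the duration link — and
YLD/YLL/DALY are derived afterwards. This keeps DALY = YLL + YLD exact
under noise while letting every one of the four ratio indices carry noise;
a single shared factor would cancel out of all ratios and make recovery
trivially exact at any noise level. With `noise_sd = 0` the per-location
MIR is exactly MIR(q), so the Spearman correlation between quality and QCI
is exactly 1 by construction.

What the generator does **not** emulate: calibrated absolute magnitudes of
real thyroid-cancer epidemiology, correlated errors across strata or
measures (real GBD estimates share modeled uncertainty), reporting
heterogeneity between registries, and uncertainty intervals. Passing the
recovery tests therefore demonstrates that the pipeline's arithmetic and
model recover a monotone latent signal under independent noise — not that
real GBD extracts satisfy these assumptions.

## Problem sizes and tolerances

Default test and acceptance problem sizes — 20 locations × 2 years × 2
sexes × 20 age bins (1,600 strata) for recovery runs, 1,000 random inputs
for additivity, 100 random matrices (n ≤ 20) for the PCA cross-check — are
small enough to run in seconds while exercising every code path; recovery
results are stable across seeds at these sizes. Unit-norm checks use 1e-12
absolute; exact-identity checks (DALY identity in generated data,
serialization round trip, fit-score reproduction) assert bitwise equality.

## Known limitations

- Absolute QCI values depend on the min–max rescale and on which strata
  enter the pooled fit; only rankings and differences are comparable across
  choices. Published absolute scores for the real 1990–2017 extract (e.g. a
  global score of 84.39) are not reproducible without that extract and the
  exact rescale convention used there.
- The external-validation route (mixed-effects correlation of QCI with the
  Healthcare Access and Quality Index) requires covariates not shipped
  here and is out of scope.
- GDR is reported without uncertainty; with scores near 0 the ratio is
  unstable, which is why zero male scores are flagged undefined.
- Uncertainty intervals present in the input (lower/upper) are validated
  but not propagated into QCI.
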