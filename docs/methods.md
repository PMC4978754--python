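# Methods

## Data model

The unit of analysis is an age × period contingency table of annualized
mortality rates, `RateTable`: A contiguous five-year age bins (rows), P
contiguous five-year period bins (columns), cell values in deaths per
100,000 person-years.  A table of death counts and population denominators
(`CountTable`) converts to rates as

    rate = deaths / (population × bin width) × 100,000 ,

dividing by the bin width so that a five-year death count is spread over
its five person-years ("annualized").  Every cell belongs to one birth
cohort via the Lexis diagonal rule cohort = period − age; a full A × P
table holds A + P − 1 cohorts, and the two corner cohorts are observed in a
single cell each.  Cohort bins are always derived, never stored: the
packaged 14 × 8 table yields 21 cohorts, 1895–1899 through 1995–1999.

Bin labels are closed integer ranges printed with an en dash ("15–19");
hyphens are accepted on input.  Rates must be strictly positive to enter
either analysis (log scale); zero-death cells are permitted in raw tables
but rejected, by cell name, at the analysis front door.  We deliberately do
not apply a continuity correction: a zero in a rate table is a data
problem the analyst should see, not silently patch.

The packaged example is the published US motorcycle-crash mortality table
(FARS numerators, census denominators, 1975–2014).  The source text
describes "15 five-year age groups" but prints 14 rows, and 14 + 8 − 1 = 21
matches both its cohort count and its rate-ratio table; this package uses
14 rows.

## Multiphase estimator

1. **Graphical phase** — `plot_age_by_cohort` draws one rate-by-age line
   per cohort; cohort effects appear as lines riding above or below their
   neighbours at equal ages.
2. **Median polish** — Tukey's iterative sweep of row and column medians on
   the natural-log rates.  Each full sweep subtracts row medians then
   column medians (rows first by default; the order is switchable and the
   measured sensitivity on the packaged table is < 1e-6 in any rate
   ratio).  Standard Tukey accounting folds the median of the accumulated
   column effects into the overall term after each row sweep and vice
   versa, keeping effect vectors median-centred.  Exact additive
   reconstruction (overall + row + column + residual = input) holds after
   every sweep to 1e-10.  Convergence: the largest absolute median removed
   in a full sweep falls below `tol` (default 1e-8); `max_iter` default
   100, with a warning and a `converged=False` flag when reached.  Medians
   of even-length vectors are the mean of the two central order
   statistics.  Missing cells are not supported and error out.
3. **Residual regression** — OLS of the A×P residuals on an intercept plus
   one indicator per non-reference cohort.  Each coefficient is the
   cohort's mean residual minus the reference cohort's mean residual, i.e.
   the log rate ratio; `RR = exp(coef)`, `CI = exp(coef ± q·SE)` with q the
   normal 0.975 quantile by default (a t option exists; with 112
   observations and 21 parameters the difference is ~1% in the interval
   width).  Every cell carries equal weight regardless of population size,
   and standard errors are homoskedastic OLS — both choices match the
   "simple linear regression" the method prescribes, and both are known
   simplifications (see Limitations).  The default reference cohort is
   1930–1934, which has the same number of cells (8) as the boomer
   sub-cohorts; it is overridable everywhere.

Significance stars mark cohorts whose 95% CI excludes 1 (equivalently
two-sided p < 0.05 under the normal approximation).  Reports never reorder
cohorts: oldest first.

## Intrinsic estimator

The effect-coded design has one row per cell and
K = 1 + (A−1) + (P−1) + (C−1) columns (sum-to-zero coding, last level of
each factor implicit).  Its rank is exactly K − 1: the null space is
spanned by the centred linear trends (ascending in age, descending in
period, ascending in cohort), which cancel on every cell because
cohort index = period index − age index + (A − 1).  `analytic_null_vector`
provides this closed form; the design builder independently recovers it by
SVD and verifies the deficiency is exactly one.

The fit is the minimum-norm least-squares solution via
`numpy.linalg.lstsq` (singular values below 1e-10 × the largest treated as
zero), which is automatically orthogonal to the null direction — the
intrinsic-estimator identification.  Fitted values coincide (to 1e-8, and
by construction) with any arbitrarily-constrained OLS, since predictions
are estimable even though individual effects are not.  Standard errors come
from σ̂²(XᵀX)⁺ with σ̂² estimated at N − (K−1) degrees of freedom; the SE of
each implicit last level uses the full block covariance.  The default
outcome scale is least squares on log rates (the only scale on which
published tables are reproducible); a Poisson-likelihood variant with log
person-year offsets (minimum-norm IRLS) is available when counts are
supplied, and agrees with the OLS path at high counts on near-additive
surfaces.

Because the minimum-norm rule splits any overall linear trend across the
three blocks by norm rather than by truth, reference-relative cohort rate
ratios from the intrinsic estimator are *not* unbiased for generating
ratios when the generating age/period effects carry strong linear
components.  The package therefore treats the intrinsic estimator as the
corroborating method — the cross-method check is rank concordance of the
boomer sub-cohort effects (positive Kendall τ and a common top-ranked
sub-cohort), not value agreement.

## Synthetic data

`APCSimulationSpec` defines a multiplicative surface
baseline × age_curve × period_trend × cohort_effects (effect vectors
normalized to geometric mean 1 so the baseline is identifiable — ratios,
which are what the pipeline estimates, are unchanged), plus an A × P
population grid and a seed.  Counts are Poisson with mean
rate × population × width / 100,000 from a `numpy.random.default_rng`
stream; an expected-count overflow guard trips above 1e12.

The default `boomer_scenario` mirrors the packaged geometry: 14 × 8 grid,
baseline 1.5 per 100,000 (the packaged table's mid-range), a smooth age
curve peaking at ages 20–24 and declining log-linearly into old age, a
shallow U-shaped period trend, cohort effects of 1.43/1.47/1.48/1.47 on
the four 1945–1964 diagonals (the published point estimates) and 1
elsewhere, and 2×10⁷ people per cell — the order of a US five-year age
band.  What the generator emulates is the multiplicative APC structure and
Poisson thinness of rare-event mortality; what it does not emulate is
overdispersion, migration between cells, exposure (miles-travelled)
heterogeneity, or any person-level structure — so passing recovery tests
demonstrate correctness of the estimators under their own model, not
robustness to real-data violations.

`recovery_experiment` repeats simulate → rebuild rates → fit, re-drawing
any zero-count cell (and logging the number of re-draws) to respect the
positive-rate contract, and reports per-cohort mean/SD of estimated rate
ratios, empirical CI coverage, and the starred fraction.

### Measured operating characteristics

Two properties of the multiphase method, measured by the recovery harness
and worth knowing before interpreting real fits:

- **Attenuation of multi-diagonal effects.**  A bump confined to a single
  diagonal passes through median polish untouched (noise-free recovery is
  exact to 1e-6).  A bump spanning four adjacent diagonals — the boomer
  scenario — occupies half the cells of several central rows, so row
  medians absorb part of it: a generating ratio of 1.5 recovers as ≈ 1.39
  even without noise.  Published multiphase rate ratios for broad cohort
  effects are therefore conservative (biased toward 1).
- **Anti-conservative intervals.**  Polish residuals are not independent
  and, with Poisson noise, not homoskedastic (sparse old-age cells are far
  noisier on the log scale); under a null scenario the nominal 5% star
  rate measures at ≈ 13% with the default scenario's populations.  The 95%
  intervals on real tables should be read as descriptive, not exact.

Both are printed, with their Monte-Carlo setups, by the test suite's
recovery test.

## Numerical and design choices

- Natural log throughout; exponentiation makes rate ratios base-invariant,
  but the CI convention assumes natural-log coefficients.
- Polish defaults tol 1e-8, max_iter 100, rows-first sweeps; all exposed on
  the CLI (`--tol`, `--max-iter`, `--sweep`).
- Reports round to 2 decimals (matching the published layout, stars
  rendered as `*` with a footnote); a full-precision companion CSV is
  always written.
- Stratified analyses (e.g. sex) re-run the whole pipeline independently
  per stratum and report side by side; a failing stratum yields a partial
  report plus an error summary rather than aborting.
- Determinism: identical input and configuration produce byte-identical
  TSV reports; every CLI run logs the package version, a configuration
  hash, and polish iteration/convergence status.
- Test problem sizes: property tests use matrices up to 6×6 and the
  recovery tests 200 replicates of the 14×8 scenario — large enough for
  stable Monte-Carlo means (SE of the mean recovered RR ≈ 0.002) while
  keeping the whole suite in the tens of seconds.

## Known limitations

- The equal-weight, homoskedastic residual regression understates
  uncertainty for sparse cells (single-cell corner cohorts enter with the
  same weight as 8-cell cohorts).
- Median polish is order-dependent in principle; both sweep orders are
  implemented and the difference is negligible on the packaged table, but
  this need not hold for heavily non-additive tables.
- No overdispersion in the simulator, no missing-cell support, no
  multiple-testing adjustment across the 20 cohort contrasts (matching the
  source analysis), and no alternative APC identification schemes beyond
  the intrinsic estimator.
- Sex-stratified results for the motorcycle data cannot be reproduced here
  because the sex-specific rate tables are not published; the stratified
  path is validated on synthetic strata instead.
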