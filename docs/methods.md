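# Methods

## Model

Every computation in the package rests on the additive two-way model for a
trait scored during seed regeneration,

    y_ij = μ + g_i + a_j + e_ij ,        e_ij ~ N(0, σ²_{e,j}) ,

with accession effects `g_i`, year effects `a_j`, and a separate residual
variance per regeneration year.  Assumptions: unreplicated randomized
plots, additivity (no accession × year interaction is estimable at ~1
observation per cell), Gaussian errors, and missingness at random.  The
last assumption is exactly what the resampling study interrogates.

Three role configurations are used:

| configuration | accessions | years | used for |
|---|---|---|---|
| A | random | fixed | year means `YE_j`, per-year `σ²_{e*,j}`, the CV screen |
| B | fixed | random | studentized-residual record test, BLUEs |
| C | random | random | variance components, heritability |

Replicated check records (rare in such archives) enter as additional
residual draws within their accession × year cell; they carry a
`replicate_index` but no block structure, since checks were not laid out
to correct field variation.

## REML engine

The engine is self-contained.  Henderson's mixed-model equations are
assembled record-wise; the (large) accession block is diagonal and is
absorbed, leaving a Schur complement no larger than years + 1.  Memory and
time are linear in records and quadratic only in years, so fixed-accession
fits with many thousands of accessions are cheap.

* REML log-likelihood via the standard identity
  `-2l = log|R| + log|G| + log|C| + y'Py + (n-p)·log 2π`, with `log|C|`
  split into the absorbed diagonal and the Schur factor.
* Per-record leverages `h_r = w_r m_r' C⁻¹ m_r` computed exactly from the
  absorbed factorization; they drive both the residual-variance updates
  and the studentized residuals.
* Optimization: EM fixed-point updates for all variance parameters
  (monotone in the restricted likelihood; the iterate trace is stored and
  tested for ascent), then an L-BFGS-B polish on the log-variance scale
  with analytic gradients, then a short run of the classic score-based
  fixed-point iteration.  The last step matters because the likelihood can
  be numerically flat near the optimum (year variances estimated from few
  year levels): log-likelihood differences fall below floating-point
  noise while the score still resolves the optimum; the refinement is
  accepted only if it shrinks the score norm.  On balanced complete
  homoscedastic grids the result matches the expected-mean-squares
  closed forms to ~1e-11.
* Convergence: relative log-likelihood change < 1e-8 (default) or 500 EM
  iterations; the `converged` flag is honest and a warning is emitted
  otherwise (flat-likelihood fits on small resampling subsets trip it
  occasionally; their parameter estimates are still at the optimum to
  within the flatness).
* Variance floor `1e-8 ×` total phenotypic variance; negative updates are
  truncated there.
* Years with fewer than `min_records_per_year_variance = 5` records share
  one pooled residual variance — a single-record year cannot support its
  own variance estimate.
* Determinism: no random initialization; accession and year levels are
  processed in sorted order.
* Identifiability: with accessions fixed, the model is parameterized in
  accession cell means (μ absorbed), so BLUEs land directly on the trait
  scale; with both factors fixed a reference constraint drops the last
  year, and disconnected designs are detected by a graph-components check
  and rejected with the offending groups named.

## Outlier correction

Step 1 (years).  From configuration A, `CV_j = sqrt(σ²_{e*,j}) / YE_j`.
A year is a candidate when `|CV_j − mean(CV)| > 3·SD(CV)`; mean and SD are
taken over all defined CVs, candidates included (no leave-one-out), and a
non-positive year mean makes the CV undefined and always flags the year
for inspection.  Candidates are removed only after adjudication:

* heritability route — removal must raise h² by more than
  `delta_h2 = 0.005` (heritabilities are reported at two decimals;
  smaller changes are invisible at that precision), or
* weather route — the year shows an anomaly with |z| ≥ 4 against its
  month-specific climatology and h² does not decrease.

By construction heritability never decreases through an adjudicated
removal; the pipeline asserts this on every run.

Step 2 (records).  On the step-1-corrected data, configuration B supplies
residuals, exact leverages and per-year variances.  Internally studentized
residuals `t_r = ê_r / (σ̂_{e,j} √(1 − h_r))` are tested two-sided against
a t reference on the effective residual degrees of freedom of the record's
variance group (`n_group − Σ h`), and Bonferroni–Holm controls the family
at α = 0.05.  All rejected records are removed in a single pass (iterative
re-fitting is deliberately not the default; the published outputs are
one-shot).  Records with leverage 1 — an accession's only record in the
fit — have residual identically zero, cannot be tested, and are listed
separately.  Internal studentization bounds |t| by roughly √n_group, which
makes the test conservative in small year groups; the family-wise error
measured on clean data is correspondingly below the nominal α.

## Deliverables

BLUEs come from configuration B with standard errors from the inverse of
the absorbed coefficient matrix at the converged variances (no
degrees-of-freedom correction).  Variance components come from
configuration C; σ²_e in the heritability

    h² = σ²_G / (σ²_G + σ²_e / Year)

is the unweighted arithmetic mean of the per-year error variances, and
*Year* is the arithmetic mean of per-accession distinct evaluation years
(the convention behind a reported 5.12; a harmonic-mean variant exists
behind a flag since parts of the breeding literature use it).  *Year* is
recomputed on the corrected data.  Descriptive summaries report
`Diff% = 100 (corrected − original)/original` per count.

One identifiability caveat documented here because it shapes two tests:
with accessions fixed and years random, the finite-sample mean of the
drawn year effects (SD `√(σ²_Y / n_years)`, ~1.5 days at the default
conditions) cannot be separated from the accession level; it shifts all
BLUEs jointly.  Bias checks therefore test the regression slope of BLUE on
truth and the level-adjusted mean bias.

## Synthetic data

The generator draws `g_i ~ N(0, σ²_G)`, `a_j ~ N(0, σ²_Y)` and
`e_ij ~ N(0, σ²_{e,j})` with per-year variances either given, equal, or
log-normal around a mean (log-SD 0.3 by default — field seasons differ in
quality).  Defaults follow winter-wheat flowering time: μ = 161 days
(10 June), σ²_G = 15.23, σ²_Y = 72.36, mean σ²_e = 9.08, 3 observation
years per accession out of 30 (~90% missing).  Missingness patterns:
`complete`, `random` (independent uniform year subsets), `block_origin`
(origin cohorts share one staggered contiguous run of years — intake
cohorts regenerated together), `block_random` (contiguous accession blocks
ignoring origin).  Sub-streams for effects, errors and missingness derive
independently from one seed, so contamination never perturbs the base
draws, and identical config + seed reproduces a dataset byte-for-byte.

An optional origin-cohort component `σ²_origin` adds a shared N(0,
σ²_origin) shift per origin group on top of the i.i.d. accession effects.
Collection hotspots draw on different breeding pools, and this cohort-level
structure is precisely what makes origin-blocked regeneration costly: with
purely i.i.d. genetics, blocked masks inflate the spread of σ̂²_Y and
σ̂²_e but not of σ̂²_G (measured directly in this package).  The resampling
analogue therefore splits its genetic variance evenly within/between
cohorts.  Within-cohort kinship, trait correlations and weather–phenotype
coupling remain out of scope — so passing tests say nothing about, e.g.,
pedigree-induced shrinkage behaviour on real collections.

Contamination helpers: `inject_record_outliers` shifts a chosen fraction
of records by ±`magnitude_sd · σ_{e,j}` (symmetric signs; real outliers'
sign structure is unknown) and returns the contaminated cell list for
scoring; `inject_outlier_year` re-draws one year's residuals with the
variance multiplied by a factor > 1.  Weather series are drawn monthly
from a temperate continental climatology (editable tables), with
anomalies injected as z-shifts; Rain is clipped at 0 and Moisture to
[0, 100] (negligible mass at the default climatology).

## Validation computations

Weather z-scores standardize each monthly value against the mean/SD of its
(month, parameter) cell across all available years — the year under
inspection included, matching how a suspicious year is judged against the
full record; a leave-one-out variant exists behind a flag.  Cells with
fewer than 3 years or zero SD yield no entries.  Severity labels: notable
at |z| ≥ 2, strong at |z| ≥ 4 (the evidence standard for removing a year).
Temporal trends are OLS slopes per calendar year; spring temperature means
March–May T.avg, unweighted.

The resampling study starts from a complete accession × year grid,
repeatedly keeps `years_kept` years per accession under one of the three
scenarios (origin-shared subsets / randomly-composed-block-shared subsets /
independent), refits BLUEs and components, and summarises the
per-accession BLUE bias and the SD of the variance-component point
estimates across replicates.  Block subsets are drawn uniformly from all
year subsets of the required size, shared within a block.

## Study sizes and numerical checks

The experiment functions (`genebankqc.experiments`) fix the study scales:
variance-component recovery on 20 replicates of 500 accessions × 30 years
at 90% missingness; the outlier-year screen on 20 seeds of 300 × 25 with
one year's variance × 25; record-test sensitivity on 20 seeds of 1000
accessions × 30 years × 6 observations with 0.3% contamination at 8 SD;
the family-wise error on 200 clean replicates of 50 × 10 × 6; the
heritability boost on 20 seeds of 200 × 20 with 1% contamination at 8 SD;
the resampling comparison on 159 accessions in the published cohort sizes
(51/42/27/15/6/6/6/6) × 6 years, 3 kept, 100 replicates per scenario.
These sizes keep each study's Monte-Carlo error below its decision margin
while the whole set finishes in about a minute on one CPU.

Two statistical ceilings worth knowing:

* the recovery check reports median *signed* relative errors — a variance
  estimated from 30 year levels has a sampling CV of √(2/29) ≈ 26%, so
  median absolute errors below 10% are unattainable at that size by any
  estimator;
* single-pass sensitivity to 8-SD shifts plateaus near 96%: a shift
  landing on a record whose own error opposes it by > 2.3 SD presents
  less than ~5.7 SD in total, below Holm thresholds at these family
  sizes.  Within-year variance masking additionally caps sensitivity near
  80% at 1% contamination, which is why the sensitivity study uses the
  sparse (0.3%) regime.

## Known limitations

* No accession × year interaction, no spatial field trend, no pedigree or
  kinship covariance, single trait at a time.
* The t reference for internally studentized residuals is approximate
  (exact inference would need a Beta transform per variance group); the
  approximation errs conservative.
* CV screening presumes a trait with a positive mean well away from zero;
  traits centred near zero make the CV meaningless (such years are flagged
  as undefined rather than silently scored).
* Weather evidence is reported, never causally interpreted: the pipeline
  says "April rainfall sat 5 SD high in the removed year", not why the
  data were bad.
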