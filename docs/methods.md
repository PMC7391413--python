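# Methods

## Model and procedure

`tempovar` treats a record-level clinical table as a sample from a
time-indexed family of distributions. Records are assigned to calendar
batches by their reference date; within each batch the distribution of one
analysis variable is estimated over a support shared by all batches. The
method makes no parametric assumption about the distributions themselves —
batches are compared non-parametrically through the Jensen–Shannon
distance and embedded geometrically. Its implicit assumptions are that (a)
the reference date is meaningful and complete enough that dropped rows do
not bias batches differentially, (b) batches contain enough records that
empirical frequencies are informative (the sampling-noise floor of the JSD
between two batches of *n* records over *k* cells grows roughly like
√(k/n)), and (c) one variable at a time is of interest — joint
distributions are out of scope.

### Batching

Granularities are ISO-8601 weeks (Monday start, identified by the Monday
date), calendar months (identified by the first of the month) and years.
The full calendar lattice between the first and last observed period is
materialised; periods with no records are, by default, kept as rows flagged
*missing* (policy `zeros`) so that batch spacing in downstream plots
reflects real time. Policy `exclude` omits them instead, for sparse data.
Missing-flagged batches carry no distribution: they are excluded from
dissimilarity matrices and embeddings, and heat maps render them in a
neutral "no data" colour distinct from an observed zero.

### Supports and distribution estimation

- Categorical: sorted unique observed labels, compared as exact strings
  after whitespace trimming (codes are case-sensitive identifiers; no case
  folding). A user-supplied support must cover every observed label.
- Continuous: `n_bins` equal-width bins over the observed [min, max]
  (default `n_bins = 100`, matching typical heat-map resolution; the
  original binning rule is configurable here for the same reason).
- Integer: one cell per integer in [min, max] unless the span exceeds
  `n_bins`, then equal-width binning.
- Dates analysed as values are converted to days since 1970-01-01 and
  treated as continuous.

Supports are always computed from the whole date range, never per batch,
so all batch distributions are comparable cell by cell. Probabilities are
relative frequencies; counts rows always sum to the records assigned to the
batch. Optional smoothing for numerical variables replaces the probability
row with a Gaussian kernel density evaluated at the bin representative
points and renormalised; the bandwidth defaults to Silverman's rule on the
batch's values, floored at one bin width when the rule degenerates to zero
(single repeated value). Kernel and bandwidth are configurable; smoothing
never alters counts.

### Dissimilarity

The distance between batches is the square root of the base-2
Jensen–Shannon divergence. It is symmetric, bounded in [0, 1] (1 exactly
for disjoint supports), zero iff the distributions are equal, and satisfies
the triangle inequality — properties the test suite asserts on randomised
inputs, with `scipy.spatial.distance.jensenshannon` as an independent
cross-check of the values. `0·log 0` terms are treated as 0.

### IGT embedding

Classical (Torgerson) multidimensional scaling: the squared dissimilarity
matrix is double-centred, eigendecomposed, and the top-`dims` non-negative
eigenvalues retained; coordinates are eigenvectors scaled by square-root
eigenvalues and variance explained is each kept eigenvalue over the sum of
positive eigenvalues. The spectral flavour was chosen over iterative
stress-minimising MDS because it is deterministic and its axes are
components of variance. JSD matrices need not be Euclidean; negative
eigenvalues are truncated to zero and their total magnitude is reported as
`negative_eigenvalue_mass` (in practice small relative to the positive
spectrum). Two numerical conventions make results reproducible across
platforms: eigenvalues are sorted in decreasing order with coordinates
ordered accordingly, and each coordinate column is sign-flipped so its
first non-zero entry is positive. Raw eigen-scaled coordinates are plotted
without per-axis rescaling, so inter-point distances approximate JSDs.

The optional trajectory fits, per dimension, a cubic smoothing spline of
coordinate against batch index, evaluated at every batch index. The
smoothing penalty defaults to generalised cross-validation (GCV), which
requires at least 5 batches; an explicit penalty works from 4. Constant
coordinate columns are passed through unchanged.

The consecutive-dissimilarity series (JSD between each batch and its
predecessor) is provided to localise abrupt changes numerically; the series
entry is paired with the date of the *later* batch, i.e. the first batch
governed by the new regime.

## Synthetic scenarios

The generator emulates multinomial code distributions over monthly batches
with the four canonical temporal-variability patterns. Effects compose in
declared order on a baseline vector: a linear trend adds `t · drift`; a
seasonal effect adds `amplitude · sin(2πt/period)`; abrupt changes and
subgroup blocks replace the working distribution from their start batch /
within their interval (so an abrupt change declared before a trend keeps
the trend running across the changepoint). The composed vector is clipped
at zero and renormalised. Records are drawn per batch from the exact batch
distribution with numpy's PCG64 generator (algorithm name and seed recorded
in the ground-truth metadata); dates are uniform within the batch period.

Preset conditions (chosen once; amplitudes/drifts are not stated by the
scenario taxonomy itself, so moderate, realistic values were fixed):

- `abrupt` — 48 monthly batches, 10 categories, uniform baseline, a
  replacement distribution at total-variation distance 0.3 entering at
  batch 25 (0-based), 500 records/batch.
- `trend` — 60 batches, 1,000 records/batch, drift ±0.0015 per batch on
  5 rising / 5 falling categories (≈ 0.44 total TV drift over the series).
- `seasonal` — 60 batches, 1,000 records/batch, period 12, amplitude
  ±0.03 per category on 5/5 categories (peak TV deviation 0.15).
- `subgroup` — two regimes alternating in 12-batch blocks.
- `mixed` — abrupt change at batch 30 plus the trend and seasonal effects,
  emulating a registry with a mid-series certificate reform.

What the generator does **not** emulate: patient/encounter structure,
weekday or holiday effects, code cardinalities in the thousands,
variable-specific missingness, or correlated variables. Passing the
recovery tests therefore shows the pipeline detects the injected shift
types at realistic batch sizes, not that it is robust to every artefact of
real EHR data.

## Numerical choices and degenerate inputs

- Probability rows are validated to sum to 1 within 1e-9; JSD inputs within
  1e-6.
- A zero-range continuous variable yields a single-cell support with a
  warning; all-identical batches embed at the origin with a warning.
- Date parsing uses one explicit strftime pattern — no format guessing —
  and unparseable rows are dropped and counted; reproducibility is
  preferred over convenience.
- Rows missing the analysed variable are excluded per variable at DTM
  estimation time (with a count), not at load time, so one loaded table
  serves many variables.
- Treatment inference marks a column numeric when every non-missing value
  parses as a number; code systems whose identifiers look numeric
  (ICD-9-CM `780.9`) therefore need the explicit `categorical` override.
- Trimming by support values copies count sub-matrices as-is; probability
  rows are only re-normalised on request, since a sub-distribution that
  sums below 1 is sometimes exactly what should be displayed.

## Problem sizes

The test suite and the acceptance script run the recovery checks at the
preset conditions above: 100 seeded realisations of the abrupt scenario and
20 each of the trend and seasonal scenarios, plus 1,000-pair metric checks
and 20 random planar configurations for the embedding oracle. The whole
suite completes in well under a minute on a single CPU.

## Known limitations

- One variable per DTM; no joint or conditional distributions.
- No changepoint significance testing or automatic clustering of batches —
  embedding coordinates and the consecutive-JSD series are exported so
  users can apply their own inference downstream.
- HTML exports are static documents (SVG with native hover tool-tips and an
  embedded JSON data block), not an interactive dashboard.
- Week-granularity seasonality uses ISO week-of-year, which shifts by a day
  across years; month granularity is the intended resolution for seasonal
  analyses.
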