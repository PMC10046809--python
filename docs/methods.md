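# Methods

## Data model and aggregation

The pipeline consumes a genes × samples matrix of already-normalized
expression ("RNA production" units; no further normalization is applied,
though a CPM transform is available for raw counts) joined to per-sample
metadata (tissue, age in months, sex). Missing values are explicit NaN,
never zero; negative values are rejected at load time.

Aggregation is **gene-first**: at each age, a gene's production is the
mean over all its valid (tissue, animal) samples, pooling the 17 tissues
and both sexes; the group value is then the mean over the group's genes.
This weights every gene equally regardless of how many of its cells
survive filtering, and is the reading consistent with per-gene production
magnitudes of the reference table. A pooled mode (all gene × sample
values averaged directly) is available via `gene_first=False`.

The per-age 95% CI is mean ± 1.96 · sd/√n over the group's per-gene
means (sample sd, n−1). The reference table's tight CIs relative to
between-gene spread indicate a standard error across thousands of genes,
which this construction matches; the original report does not state its CI
recipe, so this is a documented package choice. Whether filtering
precedes the table-level aggregation is likewise unstated; the pipeline
runs the CV filter first by default and both orders are reachable through
the API.

## CV filter

For each (gene, tissue, age) cell the coefficient of variation is sample
sd / mean over the 5–6 replicate animals; the cell is excluded iff
CV ≥ 1 (threshold configurable, must be > 0) or its mean is zero. The
motivation is between-animal variance within one experiment, so the
within-cell scope is the default; a genome-wide per-gene variant
(`scope="global"`) masks whole genes instead. The filter is monotone in
the threshold. Cells with fewer than two replicates cannot be filtered
and raise.

Detection power is limited at n=6: for right-skewed (log-normal)
replicate noise the sample CV is biased well below its true value, so a
gene with true CV 1.5 is caught in only ≈38% of its cells (and even true
CV 8 in ≈83%). The filter's effective role is separation — ordinary
CV-0.3 genes are essentially never removed (<0.1%) — not complete
elimination of the high-variance population, and the property tests pin
that separation.

## Trends and slope comparison

All regressions run on the per-age aggregated means (10 points for the
full grid), one point per age with equal weights — this is required to
reproduce the reference statistics, which are functions of the table, not
of per-sample values. `fit_line` reports slope, intercept, slope SE,
t (n−2 df, two-sided), Pearson r with its own two-sided p, RSS and Sxx.
Flat series return slope 0 with r reported as 0, p = 1 and a degeneracy
flag; perfect fits return zero RSS with infinite t and a flag rather than
raising (both arise routinely on noiseless synthetic data).

Slope equality is tested with the pooled-residual-variance F
(df (1, n₁+n₂−4)); zero pooled variance yields a flagged degenerate
comparison (F = 0/p = 1 for identical slopes, F = ∞/p → 0 otherwise).
Polynomial or spline trends and estimated-breakpoint segmented regression
are out of scope by design: with 10 time points and 5–6 heterogeneous
animals per cell, the a-priori 9-month breakpoint (physiological peak of
development) is the only segmentation the data support. Segments are
closed — the breakpoint age belongs to both — giving 4- and 7-point fits
on the standard grid.

On this construction the segment comparisons give F = 0.86, df (1,4),
p = 0.4067 on 1–9 months and F = 2.56, df (1,10), p = 0.1406 on 9–27
months. Published values pair these F's with the opposite interval
labels, which is inconsistent with their own degrees of freedom and
p-values; every comparison here therefore carries its df explicitly, and
the df-consistent pairing is the one asserted in tests.

## Ratio and stages

The ratio series is the raw quotient of HG and IntG per-age means (not
re-normalized to its own average; only the raw ratio reproduces the
reference interval slopes +0.003 and −0.011 per month). Stage summaries
use closed intervals with shared endpoints — boundary ages (6, 15, 21
months) belong to both adjacent stages, matching the grid. The 9–18 month
window of the post-peak decline claim spans a stage boundary and is
exposed as an explicit interval, not a stage. Two-point stages report the
two-point slope with a low-n flag.

## Gene catalog and blocks

Partitioning is exact-match on whitespace-trimmed symbols, case-sensitive
by default (mouse symbols are case-meaningful); a case-insensitive mode
casefolds everything, and only there can the both-groups duplicate rule
fire organically — it is implemented as a standalone predicate
(`flag_duplicates`) plus an explicit `duplicate_flagged` override so
either reading is available. Flagged names are removed from both groups;
counts always satisfy n_HG + n_IntG + n_removed = universe size.
Housekeeping names absent from the universe go to a reconciliation record,
not an error. An optional numeric-suffix prefix expansion
(`expand_prefix_variants`, default off) approximates "variant" inclusion;
since the original expansion rule is unspecified, cohort-scale counts
(35,630 / 5,101 / 30,529) are reproducible only with the originally
resolved list.

Blocks resolve against the catalog with unresolved names reported, never
dropped silently; the DNA-repair block must resolve within HG. The
shipped 56-gene repair list is a curated default spanning the major
repair pathways — the original set is cited, not listed — so block-level
numbers (e.g. a 241.71 start level) are reproducible only with the
original list and cohort. Block reports emit both the fitted start level
(early-segment prediction at the first age) and the observed first-age
mean, since "level − decline per month" summaries are ambiguous between
the two.

## Synthetic cohorts

The generator emulates the cohort structure: value(g,t,a,k) =
baseline_g · tissue_t · trend_G(a)/trend_G(a₀) · noise, with per-gene
log-normal baselines, log-normal tissue factors, piecewise-linear group
trends around the breakpoint and log-normal replicate noise of exact unit
mean and configured CV. Baselines and tissue factors are rescaled to
exact configured means, so the configured group trends are the exact
expectations of the aggregated series — noiseless recovery is then a
machine-precision identity, and noisy recovery a clean Monte-Carlo check.
Multiplicative log-normal noise (rather than negative-binomial counts)
matches the normalized-units input; a count-emitting wrapper could reuse
the same expectations.

Defaults are the study conditions: 17 tissues, ages
{1,3,6,9,12,15,18,21,24,27} months, 6 animals per cell (3M+3F; 5 gives
3M+2F), HG/IntG start levels 496.39/135.49, early slopes
−3.0446/−0.9222 units per month, breakpoint 9 months. Values the study
does not state were fixed once at field-plausible levels: a single
post-breakpoint slope multiplier of 0.43 (the HG late/early ratio; the
config carries one factor for both groups), baseline log-sd 1.0 (strongly
right-skewed per-gene levels, consistent with a small fraction of genes
carrying most production), tissue log-sd 0.5, replicate CV 0.3, and 5% of
genes at CV 1.5 for the filter to catch. Randomness uses one seed with
per-component substreams (baselines, tissue factors, high-variance
assignment, noise), so cohorts are reproducible and components
independently perturbable.

What the generator does not emulate: tissue-specific biology or
heterochronicity, sex effects on trends, gene–gene correlation, and (by
default) the full 35,630-gene scale — scale is configurable. Passing
tests therefore certify the statistical machinery and its calibration,
not the biological conclusions on real data.

## Calibration and recovery harnesses

`calibration_run` estimates the F test's type-I rate (equal configured
slopes) or power by simulating cohorts, aggregating through the standard
pipeline and testing at α; an exact binomial CI accompanies the rate. The
null configuration uses equal group levels, equal group sizes and a
single straight-line trend (late factor 1): the pooled-variance test
assumes equal residual variances and a correctly specified mean, and a
kinked common trend would add lack-of-fit to the residuals, making the
test spuriously conservative — the harness validates the machinery at its
nominal level under its own assumptions. Measured: rejection rate 0.057
(95% CI 0.043–0.073) at nominal 0.05 over 1000 replicates
(`analysis/05_calibration.py`).

`slope_recovery` fits each simulated cohort's group series (optionally on
a segment; on the pre-breakpoint segment the configured early slopes are
the exact truth) and reports the Monte-Carlo mean and standard error of
the estimates.

## Problem sizes and numerics

Repeated-simulation work (calibration at 1000 replicates, 20-cohort
recovery) uses reduced cohorts (tens of genes, 3 tissues for calibration;
2000 genes, 17 tissues for recovery) — the statistics operate on
aggregated 10-point series, so the test's behaviour is governed by the
aggregated noise level, not the raw cohort size. Coverage ties break by
descending production then lexicographic name for determinism. Pipeline
report bundles are byte-identical under a fixed config and seed (no
timestamps; config hash and seed recorded in the run log).
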