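# Methods

This note documents the models, conventions and numerical choices behind
`trackwise`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and data model

All coordinates are 0-based half-open (`[start, end)`), the BED convention;
readers convert 1-based closed inputs (GTF/GFF3, tabular files declared as
such) by decrementing the start. Chromosome names are compared after
stripping a leading `chr` prefix (case-sensitive otherwise), which serves as
the testable proxy for "all inputs belong to the same reference genome":
a track sharing no chromosome with the annotation is a validation error,
extra track chromosomes are a warning. Intervals within a track may overlap;
each is assigned independently. Missing values are carried as a single
dataset-wide sentinel rendered `not-defined` in reports (NaN/None inside the
pandas matrix).

## Scales of measurement

Every value column is classified as binary, nominal, ordinal, interval or
rational. Automatic inference maps numeric columns to rational (all defined
values > 0, so the geometric mean exists) or interval, and non-numeric
columns with exactly two / more than two distinct values to binary /
nominal. Ordinal is **never** inferred: a level order is semantics, not
syntax, and must be declared (constructor or config `ordinal_levels` /
`binning_columns`). Declared scales are validated against the values; any
mismatch is a named error, never a silent coercion.

## Aggregation

Each interval is assigned to the feature minimising the gene-body gap
(0 for any overlap, otherwise the bases strictly between interval and
feature; strand ignored) subject to `max_distance` (default 10 000 bp, a
conventional promoter-proximal window). Equidistant candidates are resolved
by the lowest (chromosome, start, feature id) — implemented by pre-sorting
features per chromosome so the first arg-min *is* the tie-break, making the
outcome platform- and input-order-independent. TSS-anchored distance is a
possible future mode; gene-body gap is the simplest reading of "closest
gene".

Per-gene collapsing uses, by default: mean for interval/rational, median
(lower median on level ranks, always a real level) for ordinal, mode (ties →
first declared level) for nominal/binary; per-column and per-technology
overrides (`max`, `min`, `median`, `mode`, `concat`, `sum`) are available,
with legality checked against the scale (e.g. mean of a nominal column is an
error). A track without value columns contributes one count column; an
untouched gene there is a real 0, not `not-defined`, because absence of
peaks is an observation. Count columns are treated as interval-scaled
(zeros are legal).

Numeric→ordinal binning (the methylation-fraction treatment) uses breaks
(default 0.2, 0.8) and labels (low/medium/high): values below the first
break take the first label, above the last break the last label, and middle
bins are closed on both ends, so 20% and 80% both fall in "medium". Binning
happens before aggregation, so the column aggregates as ordinal.

## Summaries

Location/dispersion follow the scale table in the README. Numerical
choices: the geometric mean is computed as `exp(mean(log v))` for overflow
safety; the sample standard deviation uses the n−1 denominator; a single
numeric value yields dispersion `not-defined` rather than an error; ordinal
quantiles are type-1 (inverse empirical CDF) on level ranks at 25/50/75%,
mapped back to levels so the result is always a real category. The
coefficient of variation is invariant under positive rescaling, matching the
pipeline's normalisation-independence goal.

Automatic groups: one per (technology, condition) pair with ≥ 2 columns
(replicate view) and one per technology across conditions (emitted even for
a single column, so every technology gets its overview); user groups come
from the config verbatim and may be singletons. Group members must share a
scale family — numeric groups render side-by-side boxplots coloured by
condition, categorical groups a grouped barplot of level frequencies.

## Pairwise testing

Dispatch on the two scales: categorical × categorical → Fisher's exact test
when the observed cross-tab is 2×2, otherwise Pearson's χ² (computed without
continuity correction, matching the textbook Σ(O−E)²/E statistic; an exact
test for larger sparse tables is not provided). Categorical × numeric →
Wilcoxon rank-sum for exactly two observed levels, Kruskal–Wallis otherwise.
Numeric × numeric → Pearson correlation (a config switch forces Spearman).
Orientation is normalised internally, so results are symmetric in their
inputs. A pair is skipped — with a recorded reason, excluded from the
correction family — when fewer than 3 complete (both-defined) observations
remain or either side is constant; a meaningful comparison needs more than
one value per side.

Correction defaults to Benjamini–Hochberg over the whole family of performed
tests (the 0.1 default gate is an FDR-style threshold; Bonferroni and
`none` are available). The gate applies uniformly to all test kinds.
Displayed p-values are rounded half-up to 3 digits, so p < 0.0005 renders
as "0" and exact integers drop their decimals.

## Report

Fixed section order: dataset overview, per-column summaries (every column
exactly once), replicate/user groups, per-technology views, the complete
pairwise table (figures only for significant pairs), and the association
heatmap. Heatmap cells hold the signed correlation coefficient for
numeric–numeric pairs and 1 − adjusted p for all other kinds (documented in
the report legend); skipped pairs are blank and the diagonal is 1. A
validator asserts the structural invariants after assembly. Rendering is
pure (no upstream mutation); Markdown is always written, HTML on request,
figures as PNGs named `section_slug__column_slug`. Reruns on identical
inputs are byte-identical up to the timestamp line.

## Synthetic data

The generator emulates a multi-condition study: non-overlapping genes placed
uniformly per chromosome; per gene and track an interval count (zero with
probability `missing_rate`, else 1 + Poisson(mean − 1)) with intervals
placed inside the gene body; per-gene values drawn from a Gaussian copula.
Margins: log-normal for rational columns (expression-like), normal for
interval, and thresholded latent normals for binary/nominal/ordinal with
declared level probabilities. Planted associations set the latent
correlation of a column pair; one mechanism therefore covers numeric,
mixed and categorical dependence. All intervals of a gene carry the gene's
value, so any within-gene aggregator reproduces it exactly.

Default study conditions: the three-technology × three-condition spec uses
500 genes, expression tracks with log-sd 0.8 and 5% dropout, sparse peak
tracks (35% dropout), and bimodal three-level methylation; the planted-pair
recovery setting uses two expression tracks with log-sd 0.25, where the
log-normal transform attenuates a latent ρ = 0.8 to an expected value
correlation of ≈ 0.795 (closed form for log-normal correlation), i.e. the
margin is nearly linear by design. Null calibration uses 20 mutually
independent columns cycling through four scale families at 500 genes.

What passing these tests shows: the pipeline recovers planted monotone/linear
structure at realistic sizes and does not fabricate associations on
independent columns. What it does not show: robustness to real-data features
the generator omits — intervals in intergenic space competing between genes,
heavy-tailed or zero-inflated signal, within-gene value heterogeneity,
correlated missingness, or batch structure.

## Problem sizes and limitations

Default verification sizes (500–1000 genes, ≤ 20 columns, tens of seeds)
were chosen so the whole suite runs in about a minute on one core while
keeping sampling error well inside the asserted tolerances. Known
limitations: one interval is assigned to exactly one feature (no
many-to-many or overlap-fraction weighting); no per-base signal (bigWig) or
sequence-level input; no batch-effect correction (group views only surface
it); PDF output and interactive dashboards are out of scope.
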