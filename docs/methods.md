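# Methods

This note records the statistical procedures the package implements,
the choices made where the underlying analysis left the design open,
and what the synthetic-data tests do and do not demonstrate.

## Per-screen re-analysis

**Quantile normalisation.** Columns (samples) are sorted, the reference
distribution is the vector of row-wise means of the column-sorted
matrix, and each column's values are replaced by the reference values
at their ranks.  Ties within a column receive the mean of the reference
values over the sorted positions the tied group occupies; this makes
the result deterministic and independent of row order.  For tie-free
(continuous) data the transform is exactly idempotent; with ties a
second application can move values slightly because tie-averaging
perturbs the pooled reference, which is why the idempotence guarantee
is stated for continuous input.  Missing values are rejected rather
than imputed — imputation policy belongs to the caller.

**Differential expression.** The per-gene statistic compares vulnerable
vs resistant group means of log2 intensities, so the effect estimate is
directly a log2 fold change.  Two tests are provided behind one
interface:

- `welch` (function default): the two-sided unequal-variance t test.
  Assumption-light, but with 2–4 replicates per group its 2–6 degrees
  of freedom cost a great deal of power.
- `moderated` (pipeline default): an empirical-Bayes moderated t.
  Per-gene pooled variances are shrunk toward a common prior fitted by
  matching the moments of log(s²) to its scaled-F sampling
  distribution (the prior degrees of freedom come from inverting the
  trigamma function; a non-positive excess variance means no detectable
  heterogeneity and the variances pool completely).  This borrows
  strength across genes and is the standard approach for microarray
  re-analysis at these replicate counts.

Genes with zero variance and equal means in both groups are defined to
have p = 1; zero variance with unequal means gives p = 0 (perfect
separation at machine precision — only reachable on synthetic data).

**Multiple testing.** Benjamini–Hochberg step-up q-values, delegated to
`statsmodels.stats.multitest` and property-tested against the
min-over-suffix definition.  Filtering keeps genes with q strictly
below `q_max` (default 0.05) and |log2FC| ≥ log2(`fold_min`) (default
1.5-fold).  Fold thresholds are interpreted on the linear scale and
applied in log2 units; input tables that report signed-linear fold
changes (−2.0 meaning a 2-fold drop) are converted at read time via the
per-screen `fc_scale` setting, because published per-screen magnitudes
below 1.5 are only consistent with a log2 reading.

## Homology harmonisation

Symbols are matched case-insensitively against a homology-group table
(columns `group_id`, `species`, `symbol`) and re-keyed to the reference
species (mouse, Title-case; human symbols are upper-cased on output to
their own convention).  Policies, each chosen because the source
analyses do not document theirs:

- **Probe-level duplicates** collapsing to one reference symbol: the
  record with the largest |log2FC| among significant ones wins
  (all records considered if none is significant).  Magnitude-based
  rather than significance-ranked selection keeps the retained effect
  size interpretable.
- **Sign conflicts** among the considered records mark the symbol
  direction-conflicted and exclude it from concordance; averaging
  would fabricate a direction, and concordance is defined on direction.
- **One-to-many homology** duplicates the record to every reference
  symbol and flags it; the expansion is counted so that record-level
  conservation (emitted + unmapped + collapsed + conflicted − expanded
  = input) can be asserted.

The fly-ortholog best-match filter drops weighted prediction scores of
2 or below (strict) and keeps every candidate tied at the maximum
surviving score.

## Concordance and candidate selection

The concordance matrix holds each reference symbol's log2 fold change
per screen, NaN where the gene did not pass that screen's filter.  A
gene's direction is `up`/`down` when every present value shares the
sign, otherwise `discordant`; its tier is the number of screens present
(0 when discordant).  Absence is ignored rather than counted as
disagreement because platform coverage differs across species.  Tier
tables report both exact-k and cumulative (≥ k) counts, since "altered
in k screens" is ambiguous between the two readings; exact-k is the
headline.  Overlap significance between two screens' gene lists uses
the hypergeometric upper tail with the universe defaulting to the
symbols measured in both screens (unmeasured genes cannot overlap).

Candidates for functional validation are the union of genes at tier ≥
`min_tier` (default 3) and genes at tier ≥ 2 annotated to a wanted
functional cluster; cluster annotations are consumed as a user-supplied
symbol → labels table, not recomputed.  Up-regulated candidates are
assigned to the knockdown arm, down-regulated to overexpression.

## Validation statistics

- **Fly eye screen**: one-way ANOVA across all lines; each line vs the
  disease-model control by a two-sided t using the pooled ANOVA error
  (N − k df); Holm–Šidák step-down adjustment.  Significant lines with
  a larger mean eye area than the control are suppressors, smaller are
  enhancers; the hit rate is 100 × modifiers/lines, rounded half away
  from zero.  Alpha defaults to 0.05 (the source figures star at 0.01
  and 0.001, but state no calling threshold).  Analysis is per fly
  (each value the average of two eyes), not per eye.
- **Mann–Whitney U**: exact permutation p by complete enumeration of
  rank assignments when n₁ + n₂ ≤ 12 (valid under ties, two-sided via
  doubled smaller tail capped at 1); otherwise the normal approximation
  with tie correction.
- **Survival**: Kaplan–Meier product-limit curves (lifelines), median
  as the first time S(t) ≤ 0.5, percent change in median between
  groups, and the Mantel–Cox log-rank test.  A group with no observed
  deaths has an undefined median and is flagged.
- **Endplate occupancy**: per-muscle percentages of fully/partially
  occupied and vacant endplates; fewer than 100 classified endplates
  per muscle triggers a warning; the fully-occupied percentage is the
  primary endpoint, compared across groups by Mann–Whitney.
- **Weights**: two-sided pooled-variance Student's t.

## Synthetic data

`gen_multiscreen` emulates the structure the meta-analysis assumes: a
shared gene universe (default 2,000 genes) measured by several screens
(default 4, species mouse/human/mouse/rat to mirror the real roster),
with planted concordant genes (default 50) shifting the vulnerable
group mean by ±`effect_log2` (default 1.0) with a common sign across
screens, planted discordant genes (default 20) flipping sign in one
randomly chosen screen, gaussian log2 noise (default sd 0.25, 4
replicates per group) and optional per-screen coverage dropout.
Species namespaces differ in case convention and are linked by a
generated homology map, so harmonisation is exercised end to end.  A
single master seed spawns per-screen substreams, making every output
bit-reproducible.  A zero effect size plants nothing: all genes are
null.

`gen_phenotypes` produces eye areas (gaussian around a 0.10 mm²
disease-control mean, sd 0.012, 12 flies per line), survival times
(exponential, untreated median 26 days, treated hazard scaled by the
hazard ratio, administrative censoring at day 150) and endplate counts
(trinomial per muscle, 120 endplates, group-specific fully-occupied
probability with the remainder split 2:1 partial:vacant).  These
magnitudes are chosen to resemble the validation experiments' scale.

What the synthetic data does **not** model: probe-level intensity
distributions of real platforms, gene–gene correlation, heteroscedastic
per-gene variances (the moderated test's full-pooling regime is the
best case for it), batch structure, or mapping ambiguity beyond simple
one-to-one homology.  Passing recovery tests therefore demonstrates
correctness of the machinery and calibration of the statistics, not
performance on real microarray data.

## Calibration facts used by the tests

Two properties shape the test tolerances.  First, Benjamini–Hochberg
controls the FDR, so on null screens the expected fraction of q < 0.05
genes is at most 0.05 (usually far below, since with no signal the
smallest q rarely clears the threshold).  Second, Holm–Šidák controls
the familywise error at exactly alpha for independent tests, so the
expected fraction of null modifier screens with zero calls is exactly
95% at alpha 0.05 — a replicate-based check against a 95% bound must
therefore carry a Monte-Carlo allowance (2 sigma of the binomial
proportion), which the calibration tests do explicitly.

At the baseline recovery conditions the moderated-t pipeline recovers
≥ 90% of planted concordant genes in the top tier.  Welch's t does not:
with 4 replicates per group, effect 1.0 and noise sd 0.25, its
per-screen power against the BH threshold is roughly 40%, which
four-screen intersection drives to almost zero.  This, not a preference
of taste, is why the pipeline defaults to the moderated test while the
plain Welch test remains available and is the `de_test` function
default.

A discordant gene can appear "concordant at tier 2" legitimately: if
the screen carrying its flipped sign fails to detect it, the remaining
screens agree.  Top-tier concordance, by contrast, requires presence in
every screen and is impossible for a discordant gene unless a sign is
misestimated outright; recovery reports count both, and the headline
zero-leakage claim is made at the top tier.

## Problem sizes

The test suite runs the full recovery study at the baseline conditions
(4 screens × 2,000 genes × 8 samples) once, null calibrations at 50
replicates of 500 genes and 40 replicate modifier screens, and the
brute-force oracles (BH/Holm–Šidák on 1,000 random vectors,
hypergeometric enumeration to universe 12, Mann–Whitney enumeration to
n = 6 + 6); the whole suite completes in well under a minute on one
CPU.  These sizes were chosen to make Monte-Carlo margins small
relative to the asserted bounds while keeping the suite fast.

## Known limitations

- Exact reproduction of the original per-screen gene lists from raw
  GEO intensities is out of scope: the original analyses' test
  statistics are undocumented, and probe annotation vintages differ.
- The deposited per-gene supplementary tables are not redistributed;
  the two checks that audit their tallies (910 kept / 218 up / 692
  down; 595 and 62 tier-list sizes) require a local copy under
  `data/external/`.
- DAVID-style functional-cluster enrichment is consumed as annotation
  input, never recomputed.
- The concordance framework treats screens as exchangeable evidence;
  it does not weight screens by sample size, platform or species
  distance.
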