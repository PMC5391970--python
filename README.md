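# concord-mn

Cross-species direction-concordance meta-analysis of differentially
vulnerable motor-neuron transcriptomes.

## The problem

In motor neuron diseases (SMA, ALS, SBMA) some motor neuron pools
degenerate early while others — notably those of the oculomotor and
other cranial nuclei — are spared until late in disease.  Because this
pattern is visible in *healthy* animals' transcriptomes, genes that
differ between vulnerable and resistant pools in normal tissue are
candidate modifiers of disease.  Several independent screens (bulk
microarray and RNA-seq, laser-captured motor neurons from human, rat
and mouse) have profiled such pools.  This package implements the
pipeline that combines them:

1. **Re-analysis** of each screen: quantile normalisation of log2
   intensities, per-gene two-group testing (Welch's t, or an
   empirical-Bayes moderated t for small replicate counts),
   Benjamini–Hochberg FDR adjustment, and filtering at q < 0.05 with
   |log2FC| ≥ log2(1.5).
2. **Homology harmonisation** of every screen to mouse official gene
   symbols, with explicit policies for probe-level duplicates,
   one-to-many homology and sign conflicts; plus the best-match filter
   for weighted ortholog-prediction (DIOPT-style) scores (> 2, ties at
   the maximum all kept).
3. **Concordance tiering**: a gene's tier is the number of screens in
   which it passes filtering with a common fold-change direction;
   screens that did not measure a gene are ignored, not counted as
   disagreement.  Pairwise quadrant summaries and a hypergeometric
   overlap test are included.
4. **Candidate selection** for functional validation: genes concordant
   in ≥ 3 screens, or concordant in ≥ 2 screens and annotated to a
   wanted functional cluster; up-regulated genes go to a knockdown arm,
   down-regulated genes to an overexpression arm.
5. **Validation statistics**: suppressor/enhancer calling in a fly eye
   modifier screen (one-way ANOVA with Holm–Šidák post-hoc vs the
   disease control), exact/asymptotic Mann–Whitney U, Kaplan–Meier
   survival with the Mantel–Cox log-rank test, endplate-occupancy
   percentages and pooled-variance Student's t.
6. **Synthetic data** with planted ground truth for every stage, so the
   whole pipeline is testable without downloads.

## Worked example

The package bundles the printed six-gene matrix of fold changes that
were significant, in a common direction, in all four screens
(Brockington: human ALS; Kaplan: mouse ALS; Murray: mouse SMA RNA-seq;
Hedlund: rat SBMA/ALS/SMA):

```python
from concord import build_matrix, tier_counts, quadrant_counts
from concord.published import cross_screen_results

matrix = build_matrix(cross_screen_results())
print(matrix.summary().round(1).to_string())
```

```
            brockington  kaplan  murray  hedlund  n_screens direction  tier
ref_symbol
Celf5              -3.3    -1.4    -2.0     -2.7          4      down     4
Col5a2             -3.1    -3.8    -3.9     -2.1          4      down     4
Pgrmc1             -1.5    -0.8    -1.6     -2.6          4      down     4
Snca               -1.3    -1.1    -1.8     -2.0          4      down     4
Stmn1              -1.4    -0.8    -1.6     -1.0          4      down     4
Hoxa5               2.9     3.5     7.1      3.7          4        up     4
```

All six genes are tier 4 — significant with the same sign in every
screen: five decreased in vulnerable motor neurons (including
alpha-synuclein, `Snca`) and one increased (`Hoxa5`).  The tier table
and a pairwise quadrant summary:

```python
counts = tier_counts(matrix)
print(counts.exact.to_string())
q = quadrant_counts("murray", "hedlund", matrix)
print(f"(+,+)={q.up_up} (-,-)={q.down_down} off-diagonal={q.up_down + q.down_up}")
```

```
   total  up  down
1      0   0     0
2      0   0     0
3      0   0     0
4      6   1     5
(+,+)=1 (-,-)=5 off-diagonal=0
```

End-to-end runs are driven by a YAML config (`concord run --config
run.yaml`) or the stage subcommands (`concord build`, `concord tiers`,
`concord quadrants`, `concord candidates`, `concord flyscreen`,
`concord survival`, `concord nmj`); `concord simulate --seed 7 --out
sim/` writes a complete synthetic input set.

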