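# External data

Journal-deposited supplementary tables are not redistributed with this
package.  Two acceptance checks audit their tallies and will fail with
a pointer here until the files are supplied:

- `rnaseq_per_gene.tsv` — the deposited per-gene RNA-seq table of the
  mouse screen (export the XLSX supplement to TSV; columns used:
  `gene`, `log2(fold_change)`, `p_value`, `q_value`).
- `concordant_2plus.tsv` / `concordant_3plus.tsv` — the deposited
  two-screen and three-screen concordance lists (TSV with a header row,
  one reference symbol per row).
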