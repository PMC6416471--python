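# erp — ER-stress ribosome profiling analysis

`erp` is a Python toolkit for the downstream analysis of paired ribosome
footprint profiling (Ribo-seq) and RNA-seq data from an ER-stress time
course in wild-type and PERK-null cells. The unfolded protein response
couples a fast PERK→eIF2α translational arm with the slower XBP1/ATF6
transcriptional arms; this package implements the statistics that
disentangle them from gene-level TPM tables, positional footprint
profiles, and polysome-gradient traces:

- **Expression programs.** Genes regulated ≥ 2-fold in any stress
  timepoint (after filtering genes with mean TPM < 2 and flooring the
  rest to TPM 4) are clustered by average-linkage hierarchical clustering
  on `1 − ρ_Spearman` of their TPM time profiles and cut into three
  programs: early induction, late induction, repression. Per-program
  effect sizes are medians of linear fold changes,
  `100·(median(2^LFC) − 1)` for induction and `100·(1 − median(2^LFC))`
  for repression.
- **Regulatory mode.** With `c = log2(cutoff)` (default cutoff 1.5),
  a gene is *mRNA + translation* repressed when `LFC_ribo ≤ −c` and
  `LFC_rna ≤ −c`, *translation-only* repressed when `LFC_ribo ≤ −c` but
  `LFC_rna > −c`, and otherwise not repressed; a cutoff scan over
  1.3–2.1 checks robustness.
- **5′ pausing.** Footprints (22–34 nt after polyA stripping and
  trimming to 34 nt) are assigned by 5′ end to AUG-anchored CDS
  coordinates; CDSs < 100 nt are dropped and 30 nt clipped at each end.
  The per-gene pausing score is the mean density at clipped positions
  ≤ 140 nt over the mean density beyond; conditions are compared with a
  two-sample KS test and the percent shift in median score.
- **Polysome P/M.** Gradient traces are segmented into the 80S monosome
  peak and the ≥ 4-some polysome region; P/M is the ratio of the
  baseline-subtracted trapezoidal AUCs.
- **Gene-set statistics.** ECDF comparisons of set vs all-expressed
  background LFCs (pooled-variance Student t), induced fractions,
  PERK-independent vs PERK-attenuated partition of XBP1/ATF6 target
  lists at 8 h, and one-sided Fisher overrepresentation with
  Benjamini–Hochberg control.
- **Synthetic data.** Every input can be generated with planted ground
  truth (program labels, regulatory modes, ER-target flags, target
  classes, known pausing ramps and P/M ratios), so the whole pipeline is
  testable end to end without any downloads.

## Worked example

Run the full pipeline on the default synthetic dataset (1,600 genes:
1,000 background, 150 early, 150 late, 200 repressed, 100 XBP1-ATF6
targets; lognormal noise σ = 0.25, seed 42):

```bash
erp run --out runs/demo
```

The run report (`runs/demo/report.json`) contains, among others:

```
expression:  n_expressed 1599, n_regulated_wt 647
programs:    sizes {early: 193, late: 204, repression: 250}
             recovery_accuracy 0.958
             repression WT medians: 50.6% (5 h), 51.7% (8 h)
regmode:     translation_only 256, mrna_and_translation 52 (cutoff 1.5)
targetsets:  independent 65, attenuated 31, unclassified 4
             fraction induced: WT 0.68, KO 0.96
enrichment:  er_targets enriched in the repression program
```

Reading: of the 1,599 expressed genes, 647 change ≥ 2-fold in wild-type
cells and split into the three programs; 95.8 % of the planted program
genes are recovered with the correct label. The repression program shows
a ~50 % median repression at the late timepoints in WT, and most
repressed genes are repressed at the level of translation only. Of the
expressed XBP1-ATF6 targets, most are induced in PERK-null cells while a
subset is down in WT — the PERK-attenuated class.

The stage commands (`erp expression`, `erp regmode`, `erp targets`,
`erp pausing`, `erp polysome`, `erp enrich`, `erp simulate`) expose the
same steps individually; see `erp --help`.

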