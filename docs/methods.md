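# Methods

This note documents the analysis model, its tunable parameters, what the
synthetic-data generators do and do not emulate, and the numerical
choices made where the design was open.

## Expression layer

Gene-level TPM tables (genes × samples) carry per-column metadata:
genotype (WT or PERK-null "KO"), timepoint in hours (0 = unstressed
control; stress timepoints 1, 2, 5, 8 h), assay (ribo = ribosome
footprints, rna = RNA-seq), replicate. Replicate columns of the same
condition are averaged at load time, before any filtering, so all
downstream statistics operate on one column per condition.

Filtering and flooring: genes with mean TPM < 2 across all samples are
removed (the filter uses raw values), then every remaining value below 4
is raised to 4. The floor exists to damp ratio noise at low expression —
a gene falling from TPM 3 to TPM 1 should not register as a 3-fold
repression. A consequence worth keeping in mind: planted or real effects
on genes whose expression sits near the floor are deliberately
attenuated, so noise-free "exactness" claims in the tests are scoped to
genes the floor never touches. The post-filter gene set is the
"expressed genes" universe — the background for every set statistic and
enrichment test.

Fold changes are log2 ratios of each condition against its own
(genotype, assay) control column; ribo and rna assays are never mixed in
one table. "Regulated" genes reach |LFC| ≥ log2(2) (inclusive) in at
least one stress timepoint.

## Program clustering

Regulated WT genes are clustered on their WT ribo TPM profiles across
the five conditions, using `1 − ρ_Spearman` as the distance (Spearman
makes any monotone transform of TPM irrelevant, so raw rows are used)
and average-linkage agglomerative clustering, cut to exactly k = 3.
Constant profiles have undefined rank correlation; their distances are
set to 1 with a warning. The linkage method is recorded in the result
and overridable.

Clusters become programs by template labeling on their mean WT LFC time
profile: negative overall mean → repression; otherwise early if the
early-half mean (1–2 h) is at least the late-half mean (5–8 h), else
late. Clusters are processed in order of decreasing |mean LFC| for
deterministic tie-breaking, and a collision of two clusters on one label
is an error (it signals a wrong k or degenerate input) reporting the
cluster means. Program effect sizes are medians of linear fold changes:
`100·(median(2^LFC) − 1)` for inductions, `100·(1 − median(2^LFC))` for
repressions. Row z-scores (population SD; zero-variance rows map to 0)
exist only for heatmap display and feed no statistic.

## Set statistics

Set-vs-background comparisons use the classical pooled-variance
two-sample Student t-test, two-sided (Welch is available behind a flag
but is not the default, since equal-variance Student is the intended
statistic). The background is the LFC distribution of *all* expressed
genes for that condition, including the set itself — no set exclusion.
"Induced" means LFC > 0; the threshold is configurable. ECDFs are
right-continuous with fractions reaching exactly 1.

## Regulatory mode

With c = log2(cutoff), cutoff 1.5 by default: translational repression
"1.5-fold or more" is inclusive (`LFC_ribo ≤ −c`); mRNA repression
"less than 1.5-fold" is strict (`LFC_rna > −c`). The repressed universe
is gated on translational repression; genes repressed only at the mRNA
level are reported as not repressed but flagged. The robustness scan
re-runs the classification per cutoff over a grid (default 1.3–2.1 in
0.2 steps), recomputing the repressed universe at each cutoff, and
reports per-mode counts and the mRNA-mode fraction. Increasing the
cutoff can only shrink the repressed set (nestedness), which is asserted
as a property.

## Target partition

Externally supplied XBP1/ATF6 target lists are first filtered to genes
with mean TPM ≥ 2 in the profiled cells. At the late timepoint (8 h by
default) targets are split by the signs of their WT and KO LFCs:
up in both → PERK-independent; up in KO and down in WT →
PERK-attenuated; anything else (including LFC exactly 0) unclassified.
The default gate is strict sign (quadrant classification); an optional
magnitude gate (e.g. log2 1.5) brackets the sign-based counts.

## Footprint processing and 5′ pausing

Reads are 5′-end assigned in 1-based AUG-anchored coordinates with no
P-site/A-site offset: the statistic of interest is positional
accumulation near the 5′ end, not codon-resolved occupancy. A trailing
run of ≥ 3 A's (the polyA-tailing artifact; run length configurable) is
stripped, reads are truncated to 34 nt, and final lengths outside
22–34 nt are discarded with full accounting (kept + discarded = input).
CDSs shorter than 100 nt are excluded and 30 nt are clipped from each
CDS end, so initiation and termination peaks never contribute.

The per-gene pausing score is the mean footprint density over clipped
positions ≤ 140 nt (inclusive boundary) divided by the mean density
beyond 140 nt. Genes need ≥ 64 footprints (configurable) and nonzero
downstream density; the score is invariant to per-gene density scaling.
Conditions are compared by a two-sample KS test on per-gene score
distributions (primary) — a pooled per-position KS is available as a
secondary diagnostic — plus the percent change in median score,
`100·(median_stress/median_control − 1)`.

A note on null calibration: the exact two-sample KS p-value is discrete
and conservative at finite sample sizes, so under the null the p
distribution sits at or slightly below U(0,1). The replicate-level
uniformity checks therefore assert the absence of anti-conservative
excess (ECDF excess over the diagonal < 0.10, empirical size at 0.05
≤ 0.10) rather than two-sided exact uniformity.

## Polysome traces

Traces are (position, A254) series. Automatic segmentation finds local
maxima with prominence above 5 % of the absorbance range; the monosome
is the highest peak in the first half of the trace (ribosomal-subunit
peaks are smaller and polysome peaks sit deeper in the gradient), its
region bounded by the adjacent valleys; the ≥ 4-some polysome region
opens at the valley after the 3-some — the second peak past the 80S —
and extends to the end of the trace. Fewer than four detected peaks is
an error directing the user to manual boundaries, which are passed
through verbatim. P/M is the ratio of trapezoidal AUCs of
absorbance-minus-baseline over the two regions; the baseline is the
trace minimum (a constant or linear baseline can be supplied), making
the ratio exactly invariant to uniform scaling and baseline shifts.
The monosome region covers the 80S peak only, excluding 40S/60S subunit
peaks.

## Enrichment

One-sided Fisher exact tests (computed as the upper hypergeometric tail,
which is vectorizable) of a gene set against GMT categories over the
expressed-gene background, BH-adjusted across tested categories,
enriched at adjusted p < 0.05. The conservative EASE variant (k − 1
successes) is available behind a flag for comparability with DAVID-style
web tools but is not the default: a defined, reproducible statistic is
preferred over mimicking a service. `exclude_and_retest` re-runs
enrichment on a set minus an exclusion list (e.g. a repression program
minus its ER targets) and reports the sizes involved.

## Synthetic generators

`generate_expression` emits a WT/KO × ribo/rna × {0,1,2,5,8 h} matrix
(20 condition columns) over a shared lognormal baseline (median 50 TPM,
log-SD 1.0), with multiplicative program effects and multiplicative
lognormal noise (σ = 0.25 on the natural log, per cell). The planted
fold profiles pin the late-timepoint medians to the study conditions —
early 80 %/89 %, late 128 %/136 %, repression 50 %/51 % in WT at
5 h/8 h, attenuated to 12 %/11 %, 9 %/26 %, 18 %/12 % in the knockout —
with plausible early-timepoint shapes (early program peaking 3–3.2-fold
at 1–2 h, late ramping, repression down throughout). 15 % of repressed
genes also drop at the mRNA level; the rest are translation-only
(flat RNA profile). 40 % of repression genes carry an ER-target flag for
enrichment checks, and 60 + 40 extra genes are planted as
PERK-independent / PERK-attenuated XBP1-ATF6 targets. Defaults: 1,000
background + 150/150/200 program genes.

What the generator does not emulate: count-level (Poisson/NB) sampling
noise and its mean–variance relation, compositional coupling between
genes (each gene's TPM is perturbed independently), isoforms, batch
effects, or correlated noise across timepoints. Passing recovery tests
therefore demonstrates the correctness and calibration of the
statistics under the planted-effect model, not robustness to every
artifact of real sequencing data.

`generate_profiles` places a fixed read budget per gene (default 2,000
reads on 2,000 genes, CDS lengths uniform on 400–2,400 nt)
multinomially over clipped positions, uniform for control; under stress
the weights at positions ≤ 140 are multiplied by the ramp factor
(default 1.3) before renormalization, so the true per-gene pausing
ratio equals the ramp factor exactly. `generate_trace` sums Gaussian
peaks (subunits, 80S, 2/3-somes, five polysome peaks) over a constant
baseline; given a target P/M, polysome amplitudes are solved in closed
form from Gaussian areas (`amp·σ·√(2π)`), making the true area ratio
known analytically. All generators are bit-reproducible from their
seed.

## Problem sizes in tests

The test suite and the acceptance script run everything at the default
generator sizes above; the null-calibration replicates use 200 genes ×
2,000 reads per replicate across 200 replicates, which is ample for the
size/uniformity properties being asserted since they are independent of
the per-replicate gene count.

## Known limitations

- Hierarchical clustering is O(n²) in regulated genes; fine at a few
  thousand genes, not intended for much larger universes.
- The pausing statistic assumes the 140-nt window boundary; biology with
  a different ramp extent needs the `window_end` parameter.
- Automatic trace segmentation expects a conventional peak order
  (subunits, 80S, 2-, 3-somes, polysomes) and resolvable valleys; noisy
  or drifting traces should use manual boundaries.
- Enrichment p-values depend on the category universe supplied; counts
  and direction replicate across annotation sources, exact p-values do
  not.
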