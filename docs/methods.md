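# Methods

## Scope and model

`chromtrans` analyses two conditions ("tissue A" = callus, "tissue B" =
seedling by default) described by three binary-ish genomic layers — peaks of
a repressive histone mark (H3K27me3), a permissive mark (H3K4me3) and open
chromatin (DHS) — plus expression. The unit of analysis is the gene: peaks
are collapsed onto genes, states are per-gene labels, and every downstream
statistic operates on gene sets. All internal coordinates are 0-based
half-open; 1-based formats (GFF3, fixedStep/variableStep wiggle) are
converted at the I/O boundary and restored on write.

### Region partition

Every base is assigned exactly one of six classes. Where genic features
collide the finer structure wins: 5′ UTR > 3′ UTR > coding exon > promoter >
intron > intergenic, applied base-wise (implemented by painting classes in
increasing precedence onto a per-chromosome label array, which makes the
partition property — class lengths sum to genome length — structural).
"Coding exon" means exon minus UTRs, since UTRs are separate classes. The
promoter is the `upstream_bp` (default 2,000 bp) immediately upstream of the
TSS on the gene's strand, clipped at chromosome edges. Peak distributions
are reported base-weighted (each covered base votes) with a
majority-label-per-peak count-weighted view as a secondary column.

### Mark assignment and differential deposition

A gene carries a mark iff its window — gene body plus 2 kb upstream of the
TSS, strand-aware and edge-clipped — overlaps at least one peak of that mark
by ≥ 1 bp (half-open semantics; a peak ending exactly at the window start
does not touch it). `min_overlap_fraction` optionally requires a fraction of
the window to be covered instead.

Differential deposition between tissues is an explicit, auditable rule
rather than a peak-caller-internal comparison: a gene is A-preferential iff
it carries the mark in A only, or carries it in both tissues and

    (mean_A + c) / (mean_B + c) >= min_fold

where the means are windowed mean signals from depth-normalized tracks,
`c` is the pseudocount (default 1.0) and `min_fold` defaults to 2.
Depth normalization scales each track down to the smaller genome-wide
integral (the simplest defensible analogue of downsampling the deeper
library); `differential_deposition` refuses tracks whose totals differ by
more than 1% so the ratio is never computed on incomparable depths. The rule
is symmetric (swapping tissues swaps the sets), and as `min_fold → ∞` it
degenerates to pure presence/absence.

### Meta-gene profiles and TSS matrices

Profiles map each gene onto fixed-width flank bins (default 1 kb / 20 bins)
and a body rescaled into equal-fraction bins (default 60). Bin value is the
**mean per-base signal**, not the sum, so flank and scaled-body bins share a
scale. Minus-strand genes are reversed so bin 0 is always 5′. Genes shorter
than the body bin count are skipped and counted, never padded — padding
would invent interpolated signal. TSS matrices use fixed-width bins over
TSS ± flank (3 kb / 100-bp bins for profile-style plots, 1 kb for the
clustering features, 5 kb available for broad heatmaps); windows clipped at
chromosome edges contribute zeros and are flagged.

### Chromatin states and transitions

State is a pure function of the two histone-mark flags: H3K4me3-only →
*active*, H3K27me3-only → *repressed*, both → *bivalent*, neither → *none*.
The *none* state keeps the function total; such genes are excluded from
transition classification, since no semantics exist for them. Between the
two tissues, the 3 × 3 grid of real states yields exactly seven classified
transitions — the six directional changes plus stable bivalent-bivalent;
stable active-active and repressed-repressed are deliberately unclassified.
Enrichment of a gene set in each transition class uses the one-sided
hypergeometric test below, with the universe defaulting to all genes with a
classified transition (configurable to all genes); significance stars are
placed at p < 0.01 (\*) and p < 0.001 (\*\*\*), and BH-adjusted q-values are
reported next to raw p since no multiple-testing convention is implied by
star thresholds.

### Hypergeometric enrichment

`hypergeometric_test(N, K, n, k)` returns the exact upper tail P(X ≥ k) via
the survival function of `scipy.stats.hypergeom`, which computes in log
space; the test suite pins it to exhaustive combinatorial enumeration over
every parameter combination with N ≤ 12 at 1e-12, and to a Monte-Carlo null
at larger sizes. Family enrichment intersects each family with the universe
first, drops empty families, and reports fold enrichment (k/n)/(K/N), raw p
and BH q, sorted by (p, label). The default universe is the TF catalog
itself (when the query is a TF subset, testing against the whole genome
would confound family membership with TF-ness). The test is one-sided
(enrichment only); being discrete it is conservative — under a random-query
null its p < 0.05 rate sits slightly below 0.05.

### Expression integration

- **Two-condition DEGs**: A-higher iff (expr_A + c)/(expr_B + c) > fold,
  strict inequality, default fold 2 and pseudocount 1.0 FPKM (the bare ratio
  rule is undefined at zero; the pseudocount also damps fold changes of
  barely-expressed genes).
- **Preferential expression**: samples are first brought onto a common level
  by median centering (each sample shifted so all medians agree). Quantile
  normalization is available (`normalize="quantile"`) but is not the
  default: forcing identical distributions assumes few changed genes, and
  when a substantial fraction of genes is genuinely elevated in the target
  tissue it compresses exactly the signal being tested. Per gene,
  Z = (mean over target samples − mean over other samples) / sd of other
  samples (ddof = 1; median/1.4826·MAD with `robust=True`), p is the
  upper-tail standard normal, and a gene is preferential iff Z > 0 and
  p < 0.05. Using the dispersion of the non-target samples makes the test
  conservative for multi-sample targets (the target mean's own error is not
  modelled), which is the safe direction for a screening call. Genes whose
  non-target samples are constant are flagged degenerate and called
  preferential iff the target mean exceeds the constant, with the smallest
  positive float standing in for p — silently dropping them would discard
  the most extreme cases.
- **k-means clustering**: features are the concatenated per-mark TSS-bin
  matrices, log1p-transformed and then standardized per bin. The log is
  essential for ChIP-style signal: windowed coverage of genes carrying the
  same mark varies several-fold with peak width and offset, and on the raw
  scale k-means splits carriers by amplitude instead of separating carriers
  from non-carriers. 10 restarts, best inertia, fixed seed; deterministic
  given the seed.
- **Venn integration**: the four intersections of {A,B}-preferential mark
  deposition × {A,B}-higher expression, with gene lists. For a repressive
  mark the anti-diagonal cells are the biologically expected majority.

## Synthetic data generator

The generator emulates the statistical structure of a two-tissue epigenome
study so that every stage is testable without any external download:

- **Genome/annotation**: 2 × 1 Mb chromosomes, 500 genes placed in disjoint
  slots sized so that no gene's assignment window (body + 2 kb upstream)
  touches a neighbour's. Gene bodies are 0.6–1.5 kb with a two-exon
  structure and UTRs when long enough. The slot construction is what makes
  mark-flag recovery *provable* rather than probable.
- **States**: each gene draws a (callus state, seedling state) pair from a
  fixed categorical covering all seven transitions plus stable and *none*
  pairs, skewed the way the biology runs (more active/bivalent genes in the
  pluripotent callus, more H3K27me3 in the seedling). Histone-mark flags
  derive from the states; DHS flags are Bernoulli (0.5 callus / 0.3
  seedling).
- **Peaks**: one peak per (gene, mark, tissue) carrying the flag, placed
  fully inside the gene's window with a ≥ 10 bp margin (so half-open
  boundary effects can never flip a flag). H3K27me3 peaks are broad domains
  spanning the window, Polycomb-style; H3K4me3 and DHS peaks are sharp
  (log-normal width, median 1 kb, σ = 0.5, clipped to the window) and
  TSS-anchored with 200-bp jitter. A gene carrying a mark in both tissues
  reuses the *same* interval in both, so the windowed mean ratio equals the
  planted amplitude ratio exactly.
- **Differential planting**: among double-carriers of each mark, a fraction
  (default 10%, split between directions) gets amplitudes
  base·√fold vs. base/√fold (base 50, fold 4); everyone else gets equal
  amplitudes. Presence/absence differences arising from the state design are
  part of the differential truth as well.
- **Signal**: tracks are peak indicator × amplitude; noise multiplies each
  amplitude by 1 + ε with ε truncated Gaussian (±2σ, σ = `noise_level`).
- **Expression**: FPKM base 2 + lognormal; planted DEGs (100 per direction)
  are ×4 in their tissue. Callus-up DEGs are drawn preferentially (70%)
  from genes with seedling-higher H3K27me3 and vice versa — the planted
  anti-correlation between the repressive mark and transcription that the
  Venn stage must expose. Noise is Gaussian on log values.
- **Panel**: 45 samples over 13 tissues (3 callus replicates), gene baseline
  N(8, 1) on a log-intensity scale with unit per-sample noise — that unit is
  the scale of the planted +4 sd effect given to 150 callus-preferential
  genes. The unit noise is always present (without it the Z-score's
  denominator would be degenerate for every gene).
- **Cluster archetypes**: the planted archetype is H3K27me3-carriage in
  callus — broad high signal around the TSS vs. none — which the k = 2
  clustering of the 1-kb TSS matrix recovers at ARI 1.0 under moderate
  noise.

What the generator does **not** emulate: read-level sampling noise, peak
callers and their artifacts, replicate structure in the ChIP data,
overlapping/nested genes, isoform diversity, batch effects in the panel,
and correlated mark co-occurrence beyond what the state design implies.
Passing recovery tests therefore demonstrates the *logic* of each stage and
its thresholds, not robustness to upstream noise sources the pipeline never
sees.

## Problem sizes and runtime

Tests and the acceptance script run the default study (500 genes, 2 Mb) in
seconds per pipeline pass; the oracle-equivalence checks use 200 genes × 500
peaks (assignment), every N ≤ 12 grid (hypergeometric), and a 100-kb toy
genome (meta-gene); null calibration uses 1,000 random queries against a
12-family catalog in a 2,683-gene universe. These sizes keep the whole suite
under half a minute while leaving every statistic well away from
small-sample edge cases.

## Known limitations

- The differential-deposition rule is deliberately simple (no replicate
  variance model, no local background); it is a reproducible stand-in for
  what two-condition studies typically delegate to peak-caller internals.
- The preferential-expression p-value treats the target mean as a single
  observation against the others' dispersion; it is conservative and should
  be read as a ranking device with a cutoff, not a calibrated error rate.
- Exact printed gene counts from any specific published study are not
  reproducible here: they depend on the original sequencing data and
  unpublished intermediates. The pipeline reproduces the *definitions* and
  demonstrates recovery on planted truth instead.
- One representative transcript per gene (longest, first on ties); no
  isoform-level resolution.
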