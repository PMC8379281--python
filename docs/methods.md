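# Methods

This note documents the models, conventions and numerical choices behind
`accessmark`: what each stage computes, what the synthetic-data generator
does and does not emulate, and where genuinely open design choices were
resolved.

## Coordinates and formats

Everything is 0-based, half-open (BED convention). BED output is BED6 with
`name="."`, `score=0`, so sorted files round-trip byte-for-byte. Readers
accept gzip. Gene annotations are tab-separated tables
(`symbol, chrom, start, end, strand, is_housekeeping`); repeated symbols are
collapsed to one record per symbol with the outermost coordinates, and
records of one symbol on multiple chromosomes or strands are rejected by
name. TSSes are `start` (+ strand) or `end − 1` (− strand), with exact
duplicate coordinates merged.

The Tn5 end adjustment shifts each fragment to `[start+5, end−4)`,
regardless of strand — the fragment representation already merges the two
read ends, so a single +5/−4 shift centers the interval on the insertion
sites. Fragments of ≤ 9 bp would collapse and are dropped (counted and
logged). The operation is intentionally not idempotent. Synthetic data is
emitted post-adjustment; the operation exists for ingesting real,
unadjusted fragment BEDs.

## Quantification

**Counting rule.** A fragment belongs to the region containing its midpoint
`floor((start+end)/2)`. Over the gap-free 10 kbp window tiling this
partitions each library exactly (per-chromosome counts sum to the library
size — a property the tests assert as an integer identity). Over gene
bodies, a midpoint is credited to *every* gene whose span contains it, so
overlapping annotations are supported (interval-tree fallback; the fast
binary-search path covers the non-overlapping case). Midpoint counting was
chosen over any overlap-fraction rule because it is exactly conservative
and insensitive to fragment length at window boundaries.

**Windows.** Chromosomes are tiled with consecutive `[k·w, (k+1)·w)`
windows (default w = 10,000 bp); the final partial window is kept and its
true length used in FPKM. Loci shorter than 500 bp are flagged in the log.

**FPKM.** `count / ((length/1000) · (library/1e6))`, where `library` is the
total fragment count of the sample (post-filter fragment totals; the
library size is the countable-unit total of the same fragments being
counted). FPKM is invariant under joint scaling of counts and library
size.

**TSS flanks.** Points expand to `[p−1000, p+1000)` (strand-aware:
upstream is 5′ of the point, so symmetric defaults give the same span on
both strands); flanks are clipped at chromosome edges and the clipped
length used.

**Low-signal filter.** Windows whose summed control-sample counts fall
below `min_total_count` (default 10, summed over the named control
samples) are excluded from all downstream matrices and the exclusion list
persisted. This emulates the removal of windows that attract few or no
reads for mappability reasons; the synthetic genome has no mappability
structure, so at default depth the filter mostly removes nothing — it is
exercised by tests directly.

**Genic/intergenic gating.** The border distance between a window and a
target is `max(t.start − w.end, w.start − t.end)`: negative on
intersection, 0 when touching under half-open adjacency, positive
otherwise. A window is *overlapping* iff its minimum distance over
same-chromosome targets is ≤ 0 — touching counts as overlapping, the
literal reading of a `≤ 0` gate in half-open coordinates. The
implementation (prefix-maximum of sorted target ends plus a bounded
back-scan) is checked against a brute-force all-pairs oracle on random
instances.

## Normalization and contrasts

**Quantile normalization.** The reference distribution is the per-rank mean
of the sorted columns; each value is replaced by the reference value at its
within-column rank, and tied values receive the mean of their tied ranks'
reference values (an all-constant column collapses to the reference mean).
The result has identical column multisets and is idempotent. ATAC windows
are quantile-normalized jointly across *all* replicates of both conditions,
then averaged within condition — normalize first, average second.

**Enrichment and MA.** ChIP enrichment is `log2((chip+c)/(control+c))`
against the histone H4 control track. The knockdown contrast is
`M = log2(kd/ctrl)`, `A = ½·log2(kd·ctrl)` on pseudocounted,
replicate-averaged, quantile-normalized values; `(M, A)` is exactly
invertible. The pseudocount is 0.1 FPKM everywhere. It is small relative
to typical gene/window FPKM at default depth (≈ 10), so it matters only
for near-empty regions, where it pulls log-ratios toward 0 rather than
±∞; doubling or halving it moves the recovered correlations by well under
the tolerance of any test.

**Correlation.** Pearson r is computed on the unbinned per-region values
(with the same axis transforms the 2D histograms display: log2 for
enrichment, log10 for ATAC FPKM), never on binned counts. Non-finite pairs
are dropped pairwise and counted. Fewer than 3 finite pairs, or zero
variance, yields NaN rather than a fabricated value.

**2D histograms.** Equal-width binning (default 100 bins per axis) on the
transformed scale over the observed or supplied range; per-bin counts plus,
when a color variable is given, per-bin mean color — counts drive opacity
and color carries signal in the three-way plots. Counts always sum to the
number of finite input points. The histogram serializes to a
self-describing text format; PNG rendering is an optional thin layer
(matplotlib, `plot` extra).

## Metagene profiles

Each gene body is split into `n_body_bins` equal spans (default 100) and
each flank — 50% of gene length per side, i.e. a 200% total window — into
`n_flank_bins` spans (default 50), so every bin covers the same fraction
of its gene and per-bin genomic resolution is equal between body and
flanks. Bin values are midpoint counts divided by span length (per-bp
density), optionally FPKM-scaled (`·1000 / library-millions`) so bins are
comparable across samples; both scales are exposed. Vectors are reversed
for − strand genes (bin 0 is always 5′-most). Flanks running off a
chromosome edge are clipped, the clipped length is used, and fully clipped
spans report 0. Genes shorter than the bin count are allowed; bins then
share bases.

Group curves report the per-bin arithmetic mean and *population* SD
(ddof = 0, so a single-gene group has SD 0) with group sizes. Expression
quartiles split genes into four groups of `floor(n/4)` with the remainder
distributed to the lowest quartiles and ties broken by stable input order
— fully deterministic.

## Clustering and enrichment

**Features.** Per gene, the concatenated body-only bin profiles (default
20 bins per track, FPKM scale, no log transform, no flanks) of the
H4K20me1 tracks across conditions. Feature rows are bit-identical to the
flankless metagene rows, which a cross-module test asserts.

**k-means.** Deterministic Lloyd iterations (assignment fixed point or 300
iterations) with greedy farthest-point seeding; restarts (default 10) walk
distinct first centers derived from the seed, and the best
within-cluster-sum-of-squares solution is kept. For tiny two-cluster
problems (≤ 32 points) the seeding instead enumerates every point pair,
which in practice recovers the exhaustive-search optimum — the tests
compare against full partition enumeration. Empty clusters are re-seeded
at the worst-fit point. Features are used raw by default (a
`standardize` switch z-scores columns first); k defaults to 10. Cluster
ids are relabeled 1..k by descending mean total signal so cluster 1 always
carries the strongest profiles.

**Stand-in differential expression.** Per-gene Welch two-sample t-test on
log2 expression, BH-corrected; direction is the sign of the kd − ctrl mean
difference where adjusted p < 0.05, else `ns`. Genes with zero variance in
both groups get p = 1 (equal means) or p = 0 (unequal). This deliberately
simple test replaces a moderated linear-model analysis and is where the
two differ most: with few replicates the Welch test is conservative (its
true size at α = 0.05 is ≈ 0.041 at 4v4 replicates, ≈ 0.034 at 3v3,
because the Satterthwaite degrees of freedom are small and random) and has
no variance moderation, so it needs either more replicates or larger
effects than limma-style tests would. The enrichment machinery accepts any
externally produced table with the same columns.

**Bubbles.** For each cluster × direction: observed = significant genes of
that direction in the cluster; expected = cluster size × global direction
frequency; Pearson chi-square without continuity correction on the 2×2
table [in-cluster: direction vs not | out-of-cluster: direction vs not];
BH across all cluster × direction tests; reported fold is
`log2((obs+0.5)/(exp+0.5))` (Haldane offset keeps it finite; raw counts
are also emitted). Degenerate tables (empty direction, empty margin) get
p = 1 and a flag; expected < 1 is flagged `low_expected` but still tested.
A 2×2 independence test was chosen over a goodness-of-fit variant because
it conditions on both margins; on the instances the tests cover the two
agree closely.

## The synthetic-data generator

**What it emulates.** Per-gene latents live on the log2 scale with explicit
correlation injection (a Gaussian copula): baseline H4K20me1 ~
N(0, 1.5²) plus a +2 log2 housekeeping boost and a 0.5·z(−log length)
short-gene slope; log2 accessibility = 1.5 · (ρ·z(me1) + √(1−ρ²)·ε) with
ρ = 0.6 by default, so the population correlation equals ρ exactly; log2
expression couples to accessibility the same way (ρ = 0.5); H4K20me3
couples negatively (−0.4) and is additionally concentrated in a random 30%
of intergenic background windows. SET8 knockdown multiplies H4K20me1 by
`kd_me1_residual` (0.1) and shrinks accessibility/expression by
`effect × w_g`, where `w_g` is the gene's control H4K20me1 rank scaled to
[0, 1] — rank scaling is robust to the heavy-tailed me1 distribution, and
the least-marked genes are essentially unchanged. Fragment libraries draw
per-region counts ∝ latent level × region length from a gamma–Poisson
(negative binomial, dispersion 0.05; Poisson at 0), with uniform fragment
starts, Gaussian lengths (200 ± 50 bp, clipped at 30 bp) and chromosome
clipping. Expression is log2 latent + N(0, 0.25²) per replicate.

**Study conditions.** Two 40 Mb chromosomes, 2000 genes with log-normal
lengths (median 20 kb, log-sd 0.8), 10% housekeeping, 4 replicates per
condition for ATAC and expression, single ChIP libraries per
mark/condition, 2×10⁵ fragments per library. Gene placement divides each
chromosome's slack among the inter-gene gaps (Dirichlet split), which
cannot overlap by construction and raises a capacity error when the genome
is too small. Four replicates (the upper end of the emulated design) were
chosen because the Welch stand-in needs the extra degrees of freedom to
reach multiple-testing-corrected significance at realistic effect sizes;
the expression noise SD of 0.25 log2 units is typical of replicate
microarray scatter. Cell-cycle timepoints are modeled as exchangeable
conditions (the relationships being emulated hold at every phase), so the
standard design has one control and one knockdown condition.

**Determinism.** Every output is a pure function of (config, seed). Each
(assay, condition, replicate) library, the latent truth, the genome and
the expression noise all use separate RNG streams derived from the master
seed via a label hash, so adding samples never perturbs existing ones —
byte-identical reruns are asserted in the tests.

**What it does not emulate** — and hence what passing recovery tests do
and do not show: no base-level sequence, mappability structure, GC bias,
duplicate reads or paired-end structure; no TSS/enhancer peak shape
(coverage is uniform within a region, so metagene shape information is
flat by construction and only *level* differences are recoverable); no
timepoint-specific dynamics; intergenic signal is homogeneous background
rather than enhancer-structured. Recovery therefore demonstrates that the
quantification, normalization, gating, clustering and enrichment machinery
measure planted couplings without bias at realistic depth and
overdispersion — not that the pipeline is robust to alignment artifacts
or copy-number structure.

**Recovered magnitudes.** The per-gene Pearson r recovered through the
full measurement path is slightly below the planted ρ (≈ 0.55 vs 0.6 at
default depth) — ordinary attenuation from counting noise and control-track
noise in the enrichment denominator, quantified by the recovery tests'
tolerance rather than corrected for.

## Pipeline

`run_pipeline` executes simulate → quantify → normalize → relate →
metagene → cluster → enrich, persisting every intermediate as TSV (with
sidecar metadata for library sizes and region lengths) so any stage can be
re-run from disk; a manifest and a run log (seeds, parameters) are
written, and identical configs reproduce byte-identical tables. The CLI
(`accessmark`) exposes one subcommand per stage plus `run-all`; exit codes
are 0 (success), 2 (config error), 3 (data error). The default demo
(2000 genes, 11 libraries) completes in well under a minute on one CPU;
tests and the acceptance script use scaled-down genomes (200–300 genes,
one chromosome) where full size adds nothing to the property being
checked.

## Known limitations

* The DE stand-in's conservatism and lack of moderation (above) is the
  largest deliberate simplification; bubble statistics accept external DE
  tables for real analyses.
* FPKM's within-library normalization cancels uniform global shifts — a
  knockdown that scales a mark down everywhere is invisible to
  within-sample ratios (the classic ChIP normalization blind spot); the
  pipeline sees the knockdown through its *differential* footprint, as the
  emulated analysis does.
* `classify_overlap` reports border distances per window against the
  nearest target only; distances within overlapping stacks of targets are
  minimized exactly but no per-target assignment is kept.
* k-means on raw heavy-tailed FPKM features tends to isolate extreme
  outlier genes as tiny clusters; the `standardize` switch and the
  reported cluster sizes let users detect and handle this.
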