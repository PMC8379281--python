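# accessmark

Integrative analysis of histone-mark ChIP-seq, ATAC-seq chromatin
accessibility and gene expression — with a synthetic-data generator that
reproduces the statistical structure the analysis assumes, so the whole
pipeline runs end-to-end with no downloads.

## The scientific problem

H4K20me1, the mono-methylation of histone H4 lysine 20 deposited by the
SET8 (KMT5A) methyltransferase, accumulates in the bodies of actively
transcribed genes — especially short genes and housekeeping genes — and
marks chromatin that is unusually accessible. Its tri-methylated relative
H4K20me3 marks compact heterochromatin and anticorrelates with
accessibility. Knocking down SET8 removes H4K20me1 and selectively reduces
both accessibility and expression at the genes that carried the mark.

`accessmark` implements the genomics side of that analysis for anyone who
wants to quantify and test these relationships:

* **Quantification** — fragment-midpoint counting over 10 kbp genome
  windows, gene bodies and TSS ± 1 kb flanks, normalized to FPKM
  (fragments per kilobase of region per million library fragments),
  with Tn5 +5/−4 end adjustment for ATAC fragments and exclusion of
  windows with too few control reads.
* **Contrasts** — ChIP enrichment as `log2((mark + c)/(H4 + c))` against a
  histone H4 control; knockdown accessibility as MA statistics
  (`M = log2(kd/ctrl)`, `A = ½·log2(kd·ctrl)`) of quantile-normalized,
  replicate-averaged window signal; per-gene Pearson correlations and
  100×100-bin 2D histograms with an optional mean-color channel.
* **Window gating** — genic vs intergenic windows by minimum border
  distance to annotated gene bodies (touching counts as overlapping).
* **Metagene profiles** — gene bodies rescaled to a common bin grid with
  flanks of 50% gene length on each side (a 200% window), grouped by
  housekeeping status or expression quartile.
* **Clustering & enrichment** — deterministic k-means (k = 10) of
  untransformed intragenic H4K20me1 bin profiles across conditions; a
  Welch-t + Benjamini–Hochberg stand-in differential-expression test; and
  per-cluster observed/expected counts of up-/down-regulated genes with
  Pearson chi-square tests, BH correction and Haldane-offset log2 folds
  (the "bubble" statistic).
* **Synthetic data** — a generator with per-gene log-normal latents whose
  couplings (H4K20me1 ↔ accessibility ↔ expression, anticorrelated
  H4K20me3), housekeeping/short-gene H4K20me1 boosts, SET8-knockdown
  effects and negative-binomial replicate noise are all explicit,
  seedable parameters — plus the ground truth needed for recovery tests.

## Worked example

Run the whole pipeline on a small simulated study (one 12 Mb chromosome,
300 genes, 50 k fragments per library):

```python
import accessmark as am
from accessmark.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo",
    synth=am.SimulationConfig(
        n_chromosomes=1, chromosome_length=12_000_000,
        n_genes=300, depth=50_000, seed=7,
    ),
)
run_pipeline(cfg)
print(open("demo/relate/gene_correlations.tsv").read())
```

```
comparison	pearson_r	p	n
me1_enrichment_vs_log10_atac	0.486499	3.13341e-19	300
me3_enrichment_vs_log10_atac	-0.266587	2.82465e-06	300
```

H4K20me1 enrichment correlates positively with accessibility and H4K20me3
negatively, as planted (the default generator coupling is 0.6 before
count-noise attenuation; this small demo runs at low depth). The
cluster-enrichment output (`demo/enrich/bubbles.tsv`) shows the same
geometry at cluster level — high-H4K20me1 clusters are strongly enriched
for genes down-regulated after SET8 knockdown, and the large low-signal
cluster is depleted of them:

```
cluster direction  cluster_size  observed  expected  log2_fold    chi2         p      padj
      8      down            14        13      4.71      1.37    23.0   1.6e-06   1.1e-05
      9      down            60        47     20.20      1.20    67.0   2.7e-16   2.7e-15
     10      down           216        31     72.72     -1.22   128.9   7.2e-30   1.4e-28
```

The same stages are available from the shell:

```bash
accessmark run-all --out demo --seed 7       # or: simulate, quantify,
accessmark cluster --out demo                # normalize, relate, metagene,
                                             # cluster, enrich individually
```

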