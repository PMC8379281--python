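"""End-to-end orchestration: simulate -> quantify -> normalize -> relate ->
metagene -> cluster -> enrich, with every intermediate persisted as TSV so
stages can be re-run from disk.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import genomic_io, metagene, normalize, quantify
from .core import FragmentSet, Genome, SignalMatrix
from .synth import CONDITIONS, SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class DataError(RuntimeError):
    """A stage failed on its input data (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    """One config drives every stage; stages hand off through ``outdir``."""

    outdir: str = "accessmark_out"
    synth: SimulationConfig = field(default_factory=SimulationConfig)
    window_width: int = 10_000
    pseudocount: float = 0.1
    min_total_count: int = 10
    k: int = 10
    n_restarts: int = 10
    n_profile_bins: int = 20
    n_hist_bins: int = 100
    alpha: float = 0.05
    n_body_bins: int = 100
    n_flank_bins: int = 50
    flank_frac: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        synth_raw = raw.pop("synth", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        synth_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(synth_raw) - synth_known
        if unknown:
            raise ConfigError(f"unknown synth config keys: {sorted(unknown)}")
        return cls(synth=SimulationConfig(**synth_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _out(config: PipelineConfig, *parts: str) -> Path:
    path = Path(config.outdir).joinpath(*parts)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> Path:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)
    return path


def _load_data(config: PipelineConfig):
    """Reload the simulated raw data layer from disk."""
    data = Path(config.outdir) / "data"
    required = [data / "chrom.sizes", data / "annotation.tsv", data / "samples.tsv"]
    for path in required:
        if not path.exists():
            raise DataError(f"missing input {path}; run the simulate stage first")
    genome = genomic_io.read_chrom_sizes(data / "chrom.sizes")
    annotation = genomic_io.read_annotation(data / "annotation.tsv")
    samples = pd.read_csv(data / "samples.tsv", sep="\t")
    fragments: dict[str, FragmentSet] = {}
    for row in samples.itertuples(index=False):
        path = data / row.path
        if not path.exists():
            raise DataError(f"missing fragment file {path}")
        fragments[row.label] = genomic_io.read_bed(
            path, genome, assay=row.assay, condition=row.condition,
            replicate=int(row.replicate), label=row.label,
        )
    expression = genomic_io.read_expression(data / "expression.tsv")
    return genome, annotation, fragments, expression


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> list[Path]:
    dataset = simulate_dataset(config.synth)
    write_dataset(dataset, Path(config.outdir) / "data")
    data = Path(config.outdir) / "data"
    return sorted(data.glob("*.tsv")) + sorted(data.glob("*.bed")) + [data / "chrom.sizes"]


def stage_quantify(config: PipelineConfig) -> list[Path]:
    """Counts in 10 kbp windows and gene bodies; low-signal window filter."""
    genome, annotation, fragments, _ = _load_data(config)
    windows = quantify.make_windows(genome, config.window_width)
    genes = quantify.genes_as_regions(annotation)
    win_counts = quantify.count_matrix(windows, fragments.values())
    controls = [l for l, fs in fragments.items() if fs.assay == "h4"]
    if not controls:
        raise DataError("no H4 control sample found for the low-signal filter")
    win_counts, excluded = quantify.filter_low_signal(
        win_counts, controls, config.min_total_count
    )
    gene_counts = quantify.count_matrix(genes, fragments.values())
    out1 = _out(config, "quant", "windows_counts.tsv")
    win_counts.to_tsv(out1, float_format=FLOAT_FMT)
    out2 = _out(config, "quant", "genes_counts.tsv")
    gene_counts.to_tsv(out2, float_format=FLOAT_FMT)
    out3 = _out(config, "quant", "excluded_windows.txt")
    out3.write_text("\n".join(map(str, excluded)) + ("\n" if excluded else ""))
    win_bed = _out(config, "quant", "windows.bed")
    with open(win_bed, "wt") as fh:
        for r in windows.frame.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t.\n")
    return [out1, out2, out3, win_bed]


def _condition_grouping(fragments: dict[str, FragmentSet], assay: str) -> dict[str, str]:
    return {l: fs.condition for l, fs in fragments.items() if fs.assay == assay}


def stage_normalize(config: PipelineConfig) -> list[Path]:
    """FPKM everywhere; quantile normalization of window ATAC across samples."""
    _, _, fragments, _ = _load_data(config)
    win_counts = SignalMatrix.from_tsv(_out(config, "quant", "windows_counts.tsv"))
    gene_counts = SignalMatrix.from_tsv(_out(config, "quant", "genes_counts.tsv"))
    win_fpkm = quantify.fpkm_normalize(win_counts)
    gene_fpkm = quantify.fpkm_normalize(gene_counts)
    atac = [l for l, fs in fragments.items() if fs.assay == "atac"]
    # quantile normalization jointly across both conditions, then averaging
    qn = normalize.quantile_normalize(win_fpkm.values[atac])
    by_cond = normalize.average_replicates(qn, _condition_grouping(fragments, "atac"))
    outs = []
    out = _out(config, "norm", "windows_fpkm.tsv")
    win_fpkm.to_tsv(out, float_format=FLOAT_FMT)
    outs.append(out)
    out = _out(config, "norm", "genes_fpkm.tsv")
    gene_fpkm.to_tsv(out, float_format=FLOAT_FMT)
    outs.append(out)
    outs.append(_write_tsv(qn, _out(config, "norm", "windows_atac_qn.tsv"),
                           index_label="region_id"))
    outs.append(_write_tsv(by_cond, _out(config, "norm", "windows_atac_bycond.tsv"),
                           index_label="region_id"))
    return outs


def stage_relate(config: PipelineConfig) -> list[Path]:
    """MA contrast, enrichment ratios, overlap gating, correlations, 2D bins."""
    genome, annotation, fragments, _ = _load_data(config)
    c = config.pseudocount
    win_fpkm = SignalMatrix.from_tsv(_out(config, "norm", "windows_fpkm.tsv"))
    gene_fpkm = SignalMatrix.from_tsv(_out(config, "norm", "genes_fpkm.tsv"))
    by_cond = pd.read_csv(_out(config, "norm", "windows_atac_bycond.tsv"),
                          sep="\t", index_col="region_id")

    def label_of(assay: str, condition: str) -> str:
        for l, fs in fragments.items():
            if fs.assay == assay and fs.condition == condition:
                return l
        raise DataError(f"no sample for assay={assay} condition={condition}")

    outs = []
    # windows: MA of ATAC kd vs ctrl + me1/me3 enrichment + gene overlap gate
    ma = normalize.ma_transform(by_cond["set8kd"], by_cond["ctrl"], pseudocount=c)
    win_table = ma.copy()
    h4 = win_fpkm.values[label_of("h4", "ctrl")]
    for mark in ("me1", "me3"):
        win_table[f"{mark}_enrichment"] = normalize.log2_enrichment(
            win_fpkm.values[label_of(mark, "ctrl")], h4, pseudocount=c
        )
    windows = quantify.make_windows(genome, config.window_width)
    windows = windows.subset(win_fpkm.values.index)
    genes = quantify.genes_as_regions(annotation)
    overlap = quantify.classify_overlap(windows, genes)
    win_table = win_table.join(overlap)
    outs.append(_write_tsv(win_table, _out(config, "relate", "windows_ma.tsv"),
                           index_label="region_id"))

    # genes: me1/me3 enrichment vs averaged ATAC FPKM, Pearson r, 2D histogram
    atac_grouping = _condition_grouping(fragments, "atac")
    atac_cols = [l for l in gene_fpkm.values.columns if l in atac_grouping]
    atac_mean = normalize.average_replicates(gene_fpkm.values[atac_cols], atac_grouping)
    gene_table = pd.DataFrame(index=gene_fpkm.values.index)
    h4_gene = gene_fpkm.values[label_of("h4", "ctrl")]
    for mark in ("me1", "me3"):
        gene_table[f"{mark}_enrichment"] = normalize.log2_enrichment(
            gene_fpkm.values[label_of(mark, "ctrl")], h4_gene, pseudocount=c
        )
    gene_table["atac_ctrl_fpkm"] = atac_mean["ctrl"]
    gene_table["log10_atac_ctrl"] = np.log10(atac_mean["ctrl"] + c)
    outs.append(_write_tsv(gene_table, _out(config, "relate", "genes_signal.tsv"),
                           index_label="region_id"))

    rows = []
    for mark in ("me1", "me3"):
        r, p = normalize.pearson_r(gene_table[f"{mark}_enrichment"],
                                   gene_table["log10_atac_ctrl"])
        rows.append((f"{mark}_enrichment_vs_log10_atac", r, p, len(gene_table)))
    corr = pd.DataFrame(rows, columns=["comparison", "pearson_r", "p", "n"])
    outs.append(_write_tsv(corr, _out(config, "relate", "gene_correlations.tsv"),
                           index=False))

    hist = normalize.hist2d_stats(
        gene_table["me1_enrichment"], gene_table["log10_atac_ctrl"],
        n_bins=config.n_hist_bins,
    )
    hist_path = _out(config, "relate", "hist2d_me1_vs_atac.txt")
    hist.to_text(hist_path)
    outs.append(hist_path)
    return outs


def stage_metagene(config: PipelineConfig) -> list[Path]:
    """HK vs non-HK H4K20me1 meta-profiles and expression-quartile profiles."""
    genome, annotation, fragments, expression = _load_data(config)

    def find(assay: str, condition: str) -> FragmentSet:
        for fs in fragments.values():
            if fs.assay == assay and fs.condition == condition:
                return fs
        raise DataError(f"no sample for assay={assay} condition={condition}")

    me1 = find("me1", "ctrl")
    profiles = metagene.profile_matrix(
        me1, annotation, genome,
        n_body_bins=config.n_body_bins, n_flank_bins=config.n_flank_bins,
        flank_frac=config.flank_frac,
    )
    hk = pd.Series(
        np.where(annotation["is_housekeeping"], "housekeeping", "non_housekeeping"),
        index=pd.Index(annotation["symbol"], name="symbol"),
    )
    hk_curves = metagene.group_profiles(profiles, hk)
    outs = [
        _write_tsv(profiles, _out(config, "metagene", "me1_ctrl_profiles.tsv")),
        _write_tsv(hk_curves, _out(config, "metagene", "hk_vs_nonhk_curves.tsv"),
                   index=False),
    ]
    ctrl_cols = [c for c in expression.columns if c.startswith("ctrl")]
    quartiles = metagene.assign_expression_quartiles(
        expression[ctrl_cols].mean(axis=1).reindex(profiles.index)
    )
    quartile_curves = metagene.group_profiles(profiles, quartiles.astype(str))
    outs.append(_write_tsv(quartile_curves,
                           _out(config, "metagene", "expression_quartile_curves.tsv"),
                           index=False))
    return outs


def stage_cluster(config: PipelineConfig) -> list[Path]:
    """k-means of intragenic H4K20me1 profiles across conditions."""
    genome, annotation, fragments, _ = _load_data(config)
    tracks = {
        l: fs for l, fs in fragments.items() if fs.assay == "me1"
    }
    if not tracks:
        raise DataError("no H4K20me1 tracks available for clustering")
    features = cl.build_profile_features(
        annotation, tracks, genome, track_order=sorted(tracks),
        n_bins=config.n_profile_bins,
    )
    result = cl.kmeans_profiles(
        features, k=config.k, n_restarts=config.n_restarts, seed=config.synth.seed
    )
    outs = [
        _write_tsv(features, _out(config, "cluster", "features.tsv")),
        _write_tsv(result.labels.to_frame(), _out(config, "cluster", "labels.tsv")),
        _write_tsv(result.centroids, _out(config, "cluster", "centroids.tsv")),
    ]
    meta = {"inertia": result.inertia, "k": result.k,
            "seed": result.seed, "n_restarts": result.n_restarts}
    path = _out(config, "cluster", "kmeans.json")
    path.write_text(json.dumps(meta, indent=0, sort_keys=True))
    outs.append(path)
    return outs


def stage_enrich(config: PipelineConfig) -> list[Path]:
    """Stand-in DE test and the cluster x direction enrichment bubbles."""
    _, _, _, expression = _load_data(config)
    labels = pd.read_csv(_out(config, "cluster", "labels.tsv"),
                         sep="\t", index_col="symbol")["cluster"]
    grouping = {c: ("set8kd" if c.startswith("set8kd") else "ctrl")
                for c in expression.columns}
    de = cl.de_test_standin(expression, grouping, alpha=config.alpha)
    bubbles = cl.cluster_de_enrichment(labels, de.loc[labels.index])
    return [
        _write_tsv(de, _out(config, "enrich", "de_calls.tsv"), index_label="symbol"),
        _write_tsv(bubbles, _out(config, "enrich", "bubbles.tsv"), index=False),
    ]


STAGES = (
    ("simulate", stage_simulate),
    ("quantify", stage_quantify),
    ("normalize", stage_normalize),
    ("relate", stage_relate),
    ("metagene", stage_metagene),
    ("cluster", stage_cluster),
    ("enrich", stage_enrich),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write a manifest; identical configs reproduce
    identical tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    manifest: dict[str, list[str]] = {}
    for name, fn in STAGES:
        logger.info("pipeline stage: %s", name)
        try:
            paths = fn(config)
        except (ConfigError, DataError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise DataError(f"stage {name!r} failed: {exc}") from exc
        manifest[name] = [str(Path(p).relative_to(outdir)) for p in paths]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
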