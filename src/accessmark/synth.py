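"""Synthetic genomes, fragment libraries and expression matrices.

The generator emulates the statistical structure the integrative analysis
assumes, so the whole pipeline runs without downloads:

* per-gene coupling between H4K20me1 enrichment and chromatin accessibility
  (a Gaussian copula on the log2 scale with a tunable target correlation),
* accessibility coupled onward to expression,
* H4K20me3 anticorrelated with accessibility and concentrated in a fraction
  of intergenic background windows,
* elevated H4K20me1 at housekeeping genes and at short genes,
* a SET8-knockdown condition that scales H4K20me1 down uniformly and reduces
  accessibility/expression in proportion to each gene's H4K20me1 rank,
* replicated libraries with negative-binomial (gamma-Poisson) count noise.

Every output is a pure function of (config, seed); each (assay, condition,
replicate) sample draws from its own RNG stream derived from the master
seed, so adding samples never perturbs existing ones.
"""
from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_COLUMNS,
    CapacityError,
    FragmentSet,
    Genome,
    validate_annotation,
)
from . import genomic_io

ASSAYS = ("atac", "me1", "me3", "h4")
CONDITIONS = ("ctrl", "set8kd")
MIN_FRAGMENT_LENGTH = 30


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    Latent gene-level quantities live on the log2 scale: ``hk_me1_boost`` is
    a log2 offset added to housekeeping genes' H4K20me1,
    ``short_gene_me1_slope`` multiplies the standardized negative log gene
    length. Couplings ``rho_*`` are target Pearson correlations of the log2
    latents; ``me3_anticorr`` must be non-positive. Knockdown effects are
    maximal fractional reductions applied in proportion to a gene's
    H4K20me1 rank; ``kd_me1_residual`` is the fraction of H4K20me1 left
    after SET8 knockdown.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 40_000_000
    n_genes: int = 2000
    hk_fraction: float = 0.1
    gene_length_log_mean: float = math.log(20_000)
    gene_length_log_sd: float = 0.8
    rho_me1_acc: float = 0.6
    rho_acc_expr: float = 0.5
    me3_anticorr: float = -0.4
    hk_me1_boost: float = 2.0
    short_gene_me1_slope: float = 0.5
    kd_me1_residual: float = 0.1
    kd_acc_effect: float = 0.6
    kd_expr_effect: float = 0.5
    n_replicates: int = 4
    depth: int = 200_000
    nb_dispersion: float = 0.05
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    seed: int = 0
    # latent scales and background rates
    sigma_log2_me1: float = 1.5
    sigma_log2_acc: float = 1.5
    sigma_log2_me3: float = 1.5
    sigma_log2_expr: float = 1.0
    expr_log2_mean: float = 5.0
    expr_noise_sd: float = 0.25
    atac_background: float = 0.1
    me1_background: float = 0.1
    me3_background: float = 0.2
    me3_hot_rate: float = 3.0
    me3_intergenic_fraction: float = 0.3
    me3_gene_offset: float = -2.0
    background_window: int = 10_000
    min_gene_length: int = 1000

    def validate(self) -> None:
        for name in ("hk_fraction", "kd_me1_residual", "kd_acc_effect",
                     "kd_expr_effect", "me3_intergenic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("rho_me1_acc", "rho_acc_expr"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if not (-1.0 <= self.me3_anticorr <= 0.0):
            raise ValueError("me3_anticorr must lie in [-1, 0]")
        if self.hk_me1_boost < 0:
            raise ValueError("hk_me1_boost must be >= 0 (log2 units)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("genome must have >= 1 chromosome of positive length")
        if self.n_genes < 0 or self.n_replicates < 1:
            raise ValueError("n_genes must be >= 0 and n_replicates >= 1")
        mean_len = math.exp(self.gene_length_log_mean + self.gene_length_log_sd ** 2 / 2)
        if self.n_genes * mean_len >= self.n_chromosomes * self.chromosome_length:
            raise ValueError("expected total gene length exceeds the genome")


def _stream(seed: int, *labels) -> np.random.Generator:
    """A named RNG stream derived from the master seed."""
    key = zlib.crc32("|".join(str(x) for x in labels).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# genome and annotation


def simulate_genome(config: SimulationConfig) -> tuple[Genome, pd.DataFrame]:
    """Simulate chromosome sizes and a non-overlapping gene annotation.

    Gene lengths are log-normal; genes are placed without overlap by
    dividing each chromosome's slack among the inter-gene gaps, which raises
    :class:`CapacityError` when the genome cannot host the requested genes.
    Strands are uniform; an ``hk_fraction`` of genes is flagged
    housekeeping. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _stream(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = Genome({c: config.chromosome_length for c in chroms})
    if config.n_genes == 0:
        empty = pd.DataFrame(
            {
                "symbol": pd.Series(dtype=str),
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "is_housekeeping": pd.Series(dtype=bool),
            }
        )
        return genome, empty
    lengths = np.maximum(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd,
                      config.n_genes),
        config.min_gene_length,
    ).astype(np.int64)
    chrom_of = rng.integers(0, config.n_chromosomes, config.n_genes)
    rows = []
    for ci, chrom in enumerate(chroms):
        idx = np.where(chrom_of == ci)[0]
        if len(idx) == 0:
            continue
        lens = lengths[idx]
        slack = config.chromosome_length - int(lens.sum()) - (len(idx) + 1)
        if slack < 0:
            raise CapacityError(
                f"{chrom} cannot host {len(idx)} genes totalling {lens.sum()} bp "
                f"within {config.chromosome_length} bp"
            )
        gaps = np.floor(rng.dirichlet(np.ones(len(idx) + 1)) * slack).astype(np.int64) + 1
        starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lens[:-1])])
        for s, l in zip(starts, lens):
            rows.append((chrom, int(s), int(s + l)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame = frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    frame["symbol"] = [f"GENE{i + 1:06d}" for i in range(len(frame))]
    frame["strand"] = rng.choice(["+", "-"], size=len(frame))
    n_hk = int(round(config.hk_fraction * len(frame)))
    hk_idx = rng.choice(len(frame), size=n_hk, replace=False)
    frame["is_housekeeping"] = False
    frame.loc[hk_idx, "is_housekeeping"] = True
    return genome, validate_annotation(frame[ANNOTATION_COLUMNS])


# ---------------------------------------------------------------------------
# latent truth


@dataclass
class SimulationTruth:
    """Per-gene latent levels (indexed by symbol) and the condition labels.

    ``table`` columns: ``me1_<cond>``, ``me3``, ``acc_<cond>``,
    ``expr_<cond>``, ``is_housekeeping``, ``length``, ``me1_weight`` (the
    knockdown rank weight, populated by :func:`apply_knockdown`).
    """

    table: pd.DataFrame
    conditions: tuple[str, ...] = ("ctrl",)

    def level(self, what: str, condition: str) -> pd.Series:
        col = "me3" if what == "me3" else f"{what}_{condition}"
        if col not in self.table.columns:
            raise ValueError(f"condition {condition!r} not populated for {what!r}")
        return self.table[col]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="symbol", float_format="%.8g")


def simulate_truth(annotation: pd.DataFrame, config: SimulationConfig) -> SimulationTruth:
    """Draw per-gene latent H4K20me1/H4K20me3/accessibility/expression levels.

    log2 H4K20me1 is a baseline Gaussian plus the housekeeping boost and the
    short-gene slope; log2 accessibility mixes the standardized log2 me1
    with independent noise so their population correlation equals
    ``rho_me1_acc``; log2 expression is coupled to accessibility the same
    way; log2 me3 couples negatively to accessibility via ``me3_anticorr``.
    All latent levels are strictly positive (they are powers of two).
    """
    config.validate()
    annotation = validate_annotation(annotation)
    if annotation.empty:
        raise ValueError("annotation must be non-empty")
    rng = _stream(config.seed, "truth")
    n = len(annotation)
    length = (annotation["end"] - annotation["start"]).to_numpy(dtype=float)
    z_short = _standardize(-np.log(length))
    hk = annotation["is_housekeeping"].to_numpy()

    log2_me1 = (
        rng.normal(0.0, config.sigma_log2_me1, n)
        + config.hk_me1_boost * hk
        + config.short_gene_me1_slope * z_short
    )
    z_me1 = _standardize(log2_me1)

    rho = config.rho_me1_acc
    log2_acc = config.sigma_log2_acc * (
        rho * z_me1 + math.sqrt(1.0 - rho ** 2) * rng.normal(0.0, 1.0, n)
    )
    z_acc = _standardize(log2_acc)

    rho_e = config.rho_acc_expr
    log2_expr = config.expr_log2_mean + config.sigma_log2_expr * (
        rho_e * z_acc + math.sqrt(1.0 - rho_e ** 2) * rng.normal(0.0, 1.0, n)
    )

    c3 = config.me3_anticorr
    log2_me3 = config.me3_gene_offset + config.sigma_log2_me3 * (
        c3 * z_acc + math.sqrt(1.0 - c3 ** 2) * rng.normal(0.0, 1.0, n)
    )

    table = pd.DataFrame(
        {
            "me1_ctrl": np.power(2.0, log2_me1),
            "me3": np.power(2.0, log2_me3),
            "acc_ctrl": np.power(2.0, log2_acc),
            "expr_ctrl": np.power(2.0, log2_expr),
            "is_housekeeping": hk,
            "length": length.astype(np.int64),
        },
        index=pd.Index(annotation["symbol"], name="symbol"),
    )
    return SimulationTruth(table=table, conditions=("ctrl",))


def apply_knockdown(truth: SimulationTruth, config: SimulationConfig) -> SimulationTruth:
    """Populate the SET8-knockdown condition from the control latents.

    Knockdown H4K20me1 is ``ctrl * kd_me1_residual`` exactly. Accessibility
    and expression shrink by their maximal effect scaled with ``w_g``, the
    gene's control H4K20me1 rank scaled to [0, 1] (rank scaling is robust to
    the heavy-tailed me1 distribution), so the least-marked genes are
    essentially unchanged.
    """
    config.validate()
    if "ctrl" not in truth.conditions:
        raise ValueError("control condition must be populated first")
    table = truth.table.copy()
    n = len(table)
    ranks = table["me1_ctrl"].rank(method="average").to_numpy() - 1.0
    w = ranks / (n - 1.0) if n > 1 else np.ones(n)
    table["me1_weight"] = w
    table["me1_set8kd"] = table["me1_ctrl"] * config.kd_me1_residual
    table["acc_set8kd"] = table["acc_ctrl"] * (1.0 - config.kd_acc_effect * w)
    table["expr_set8kd"] = table["expr_ctrl"] * (1.0 - config.kd_expr_effect * w)
    return SimulationTruth(table=table, conditions=truth.conditions + ("set8kd",))


# ---------------------------------------------------------------------------
# fragment libraries


def background_windows(
    annotation: pd.DataFrame, genome: Genome, config: SimulationConfig
) -> pd.DataFrame:
    """Intergenic background windows with their H4K20me3-hot flags.

    The intergenic complement of the annotation is chopped into
    ``background_window``-bp pieces; a ``me3_intergenic_fraction`` of them is
    flagged H4K20me3-hot. Derived from the master seed only, so every sample
    sees the same background.
    """
    rng = _stream(config.seed, "background")
    rows = []
    for chrom in genome:
        size = genome[chrom]
        genes = annotation[annotation["chrom"] == chrom].sort_values("start")
        cursor = 0
        gaps = []
        for s, e in zip(genes["start"], genes["end"]):
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            gaps.append((cursor, size))
        for gs, ge in gaps:
            starts = np.arange(gs, ge, config.background_window, dtype=np.int64)
            ends = np.minimum(starts + config.background_window, ge)
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame["me3_hot"] = rng.random(len(frame)) < config.me3_intergenic_fraction
    return frame


def _region_rates(
    assay: str,
    condition: str,
    truth: SimulationTruth,
    annotation: pd.DataFrame,
    background: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Concatenated (gene + background) regions and per-bp emission rates."""
    genes = annotation[["chrom", "start", "end"]].copy()
    levels = truth.table.loc[annotation["symbol"]]
    if assay == "atac":
        gene_rate = truth.level("acc", condition).loc[annotation["symbol"]].to_numpy()
        bg_rate = np.full(len(background), config.atac_background)
    elif assay == "me1":
        gene_rate = truth.level("me1", condition).loc[annotation["symbol"]].to_numpy()
        bg_rate = np.full(len(background), config.me1_background)
    elif assay == "me3":
        gene_rate = levels["me3"].to_numpy()
        bg_rate = np.where(
            background["me3_hot"].to_numpy(), config.me3_hot_rate, config.me3_background
        )
    elif assay == "h4":
        # uniform nucleosome density
        gene_rate = np.ones(len(genes))
        bg_rate = np.ones(len(background))
    else:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    regions = pd.concat(
        [genes, background[["chrom", "start", "end"]]], ignore_index=True
    )
    rates = np.concatenate([gene_rate, bg_rate])
    return regions, rates


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson counts with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    return rng.poisson(lam)


def simulate_fragments(
    truth: SimulationTruth,
    annotation: pd.DataFrame,
    genome: Genome,
    assay: str,
    condition: str,
    replicate: int,
    config: SimulationConfig,
    return_counts: bool = False,
):
    """Draw one sequencing library as a sorted fragment BED table.

    Expected per-region counts are proportional to the assay-relevant latent
    level times region length; counts are negative-binomial
    (``nb_dispersion``; Poisson at 0). Fragment starts are uniform within
    the region; lengths are Gaussian clipped at 30 bp and fragment ends are
    clipped to the chromosome. Deterministic given (config, seed, assay,
    condition, replicate).
    """
    config.validate()
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if condition not in truth.conditions and assay != "h4":
        raise ValueError(f"condition {condition!r} not populated in truth")
    if config.depth < 0:
        raise ValueError("depth must be >= 0")
    annotation = validate_annotation(annotation)
    rng = _stream(config.seed, "fragments", assay, condition, replicate)
    background = background_windows(annotation, genome, config)
    regions, rates = _region_rates(assay, condition, truth, annotation, background, config)
    lengths_bp = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    weights = rates * lengths_bp
    label = f"{assay}_{condition}_r{replicate}"
    empty = FragmentSet(
        pd.DataFrame({"chrom": pd.Series(dtype=str),
                      "start": pd.Series(dtype=np.int64),
                      "end": pd.Series(dtype=np.int64)}),
        assay=assay, condition=condition, replicate=replicate, label=label,
    )
    if config.depth == 0 or weights.sum() == 0:
        counts = np.zeros(len(regions), dtype=np.int64)
        fs = empty
    else:
        mu = config.depth * weights / weights.sum()
        counts = _nb_counts(mu, config.nb_dispersion, rng)
        total = int(counts.sum())
        if total == 0:
            fs = empty
        else:
            r_start = np.repeat(regions["start"].to_numpy(), counts)
            r_len = np.repeat(lengths_bp, counts)
            chroms = np.repeat(regions["chrom"].to_numpy(), counts)
            starts = (r_start + np.floor(rng.random(total) * r_len)).astype(np.int64)
            frag_len = np.maximum(
                np.round(rng.normal(config.fragment_length_mean,
                                    config.fragment_length_sd, total)),
                MIN_FRAGMENT_LENGTH,
            ).astype(np.int64)
            chrom_sizes = pd.Series({c: genome[c] for c in genome})
            max_end = chrom_sizes.loc[chroms].to_numpy()
            starts = np.minimum(starts, max_end - MIN_FRAGMENT_LENGTH)
            ends = np.minimum(starts + frag_len, max_end)
            frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
            fs = FragmentSet(
                frame, assay=assay, condition=condition,
                replicate=replicate, label=label,
            ).sorted()
    if return_counts:
        index = pd.Index(
            list(annotation["symbol"])
            + [f"bg:{c}:{s}-{e}" for c, s, e in
               zip(background["chrom"], background["start"], background["end"])],
            name="region",
        )
        return fs, pd.Series(counts, index=index)
    return fs


# ---------------------------------------------------------------------------
# expression matrix


def simulate_expression(
    truth: SimulationTruth,
    config: SimulationConfig,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """log2 expression values per gene and replicate.

    Per sample: ``log2(latent expression) + Gaussian noise`` (i.e. the latent
    level times log-normal noise, on the log2 scale). Columns are ordered
    control replicates first, then knockdown.
    """
    config.validate()
    if config.n_replicates < 2:
        warnings.warn(
            "fewer than 2 replicates per condition: the stand-in differential "
            "expression test will not be applicable"
        )
    cols = {}
    for cond in conditions:
        latent = np.log2(truth.level("expr", cond).to_numpy())
        for rep in range(1, config.n_replicates + 1):
            rng = _stream(config.seed, "expression", cond, rep)
            noise = rng.normal(0.0, config.expr_noise_sd, len(latent))
            cols[f"{cond}_r{rep}"] = latent + noise
    return pd.DataFrame(cols, index=truth.table.index.copy())


# ---------------------------------------------------------------------------
# standard dataset


@dataclass
class Dataset:
    """Everything one simulated study emits, in memory."""

    genome: Genome
    annotation: pd.DataFrame
    truth: SimulationTruth
    fragments: dict[str, FragmentSet]
    expression: pd.DataFrame
    config: SimulationConfig

    def atac_samples(self, condition: str | None = None) -> list[FragmentSet]:
        out = [fs for fs in self.fragments.values() if fs.assay == "atac"]
        if condition is not None:
            out = [fs for fs in out if fs.condition == condition]
        return out


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate the standard study design.

    ATAC libraries get ``n_replicates`` per condition; ChIP tracks
    (H4K20me1 ctrl/kd, H4K20me3 ctrl, H4 control) are single libraries.
    """
    genome, annotation = simulate_genome(config)
    truth = apply_knockdown(simulate_truth(annotation, config), config)
    fragments: dict[str, FragmentSet] = {}
    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            fs = simulate_fragments(truth, annotation, genome, "atac", cond, rep, config)
            fragments[fs.label] = fs
    for assay, cond in (("me1", "ctrl"), ("me1", "set8kd"), ("me3", "ctrl"), ("h4", "ctrl")):
        fs = simulate_fragments(truth, annotation, genome, assay, cond, 1, config)
        fragments[fs.label] = fs
    expression = simulate_expression(truth, config)
    return Dataset(genome, annotation, truth, fragments, expression, config)


def write_dataset(dataset: Dataset, outdir: str | Path) -> pd.DataFrame:
    """Write a dataset to disk and return the sample manifest.

    Emits chrom.sizes, annotation.tsv, truth.tsv, expression.tsv, one BED
    file per sample, and samples.tsv listing assay/condition/replicate per
    emitted file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomic_io.write_chrom_sizes(dataset.genome, outdir / "chrom.sizes")
    genomic_io.write_annotation(dataset.annotation, outdir / "annotation.tsv")
    dataset.truth.to_tsv(outdir / "truth.tsv")
    genomic_io.write_expression(dataset.expression, outdir / "expression.tsv")
    rows = []
    for label, fs in dataset.fragments.items():
        path = outdir / f"{label}.bed"
        genomic_io.write_bed(fs, path)
        rows.append((label, fs.assay, fs.condition, fs.replicate, path.name))
    manifest = pd.DataFrame(
        rows, columns=["label", "assay", "condition", "replicate", "path"]
    )
    manifest.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return manifest
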