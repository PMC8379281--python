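"""Relative-length scaled gene-body profiles and group averages.

Each gene body is rescaled to a fixed number of bins so genes of different
sizes occupy the same horizontal space; flanks proportional to gene length
(default 50% each side, i.e. a 200% total window) are binned the same way.
Bin values are per-bp fragment-midpoint densities, optionally put on an
FPKM-like scale, and profiles are 5'->3' oriented (bin 0 is 5'-most, so
minus-strand profiles are reversed).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FragmentSet, Genome, validate_annotation

DEFAULT_BODY_BINS = 100
DEFAULT_FLANK_BINS = 50
DEFAULT_FLANK_FRAC = 0.5


def _bin_edges(
    start: int, end: int, n_body_bins: int, n_flank_bins: int, flank_frac: float
) -> np.ndarray:
    """Unclipped bin edges: upstream flank, body, downstream flank."""
    flank = flank_frac * (end - start)
    parts = []
    if n_flank_bins > 0:
        parts.append(np.linspace(start - flank, start, n_flank_bins + 1)[:-1])
    parts.append(np.linspace(start, end, n_body_bins + 1)[:-1])
    if n_flank_bins > 0:
        parts.append(np.linspace(end, end + flank, n_flank_bins + 1))
    else:
        parts.append(np.array([float(end)]))
    return np.concatenate(parts)


def bin_labels(n_body_bins: int, n_flank_bins: int) -> list[str]:
    """Column labels: u* upstream, b* body, d* downstream (5'->3')."""
    return (
        [f"u{i}" for i in range(n_flank_bins)]
        + [f"b{i}" for i in range(n_body_bins)]
        + [f"d{i}" for i in range(n_flank_bins)]
    )


def profile_matrix(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    genome: Genome,
    n_body_bins: int = DEFAULT_BODY_BINS,
    n_flank_bins: int = DEFAULT_FLANK_BINS,
    flank_frac: float = DEFAULT_FLANK_FRAC,
    scale: str = "fpkm",
) -> pd.DataFrame:
    """Genes x bins profile matrix for one sample.

    ``scale='fpkm'`` divides the per-bp density by library size so bins are
    comparable across samples (count / span_kb / library_millions);
    ``scale='density'`` leaves raw midpoints per bp. Flanks running off a
    chromosome edge are clipped and the clipped span length is used; fully
    clipped spans get value 0. Short genes are allowed (bins may share
    bases).
    """
    if scale not in ("fpkm", "density"):
        raise ValueError(f"unknown scale {scale!r}")
    if n_body_bins < 1 or n_flank_bins < 0:
        raise ValueError("need n_body_bins >= 1 and n_flank_bins >= 0")
    annotation = validate_annotation(annotation).reset_index(drop=True)
    n_bins = n_body_bins + 2 * n_flank_bins
    out = np.zeros((len(annotation), n_bins))
    mids_by_chrom = {
        chrom: np.sort((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        for chrom, grp in fragments.frame.groupby("chrom", sort=False)
    }
    lib_millions = max(fragments.library_size, 1) / 1e6
    for chrom, genes in annotation.groupby("chrom", sort=False):
        mids = mids_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        chrom_len = genome[chrom]
        edges = np.stack(
            [
                np.clip(
                    _bin_edges(s, e, n_body_bins, n_flank_bins, flank_frac),
                    0.0,
                    float(chrom_len),
                )
                for s, e in zip(genes["start"], genes["end"])
            ]
        )
        # one searchsorted over all genes' edges at once
        idx = np.searchsorted(mids, edges.reshape(-1)).reshape(edges.shape)
        counts = np.diff(idx, axis=1).astype(float)
        spans = np.diff(edges, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(spans > 0, counts / spans, 0.0)
        if scale == "fpkm":
            dens = dens * 1000.0 / lib_millions
        minus = (genes["strand"].to_numpy() == "-")
        dens[minus] = dens[minus, ::-1]
        out[genes.index.to_numpy()] = dens
    return pd.DataFrame(
        out,
        index=pd.Index(annotation["symbol"], name="symbol"),
        columns=bin_labels(n_body_bins, n_flank_bins),
    )


def scaled_gene_profile(
    fragments: FragmentSet,
    gene: pd.Series,
    genome: Genome,
    n_body_bins: int = DEFAULT_BODY_BINS,
    n_flank_bins: int = DEFAULT_FLANK_BINS,
    flank_frac: float = DEFAULT_FLANK_FRAC,
    scale: str = "fpkm",
) -> np.ndarray:
    """Profile vector of a single gene (row of an annotation table)."""
    annotation = pd.DataFrame([gene])
    mat = profile_matrix(
        fragments, annotation, genome,
        n_body_bins=n_body_bins, n_flank_bins=n_flank_bins,
        flank_frac=flank_frac, scale=scale,
    )
    return mat.iloc[0].to_numpy()


def group_profiles(profiles: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-group, per-bin mean and population SD curves.

    Every gene must carry a label; empty groups (labels without members
    cannot occur by construction) and unlabeled genes raise. Returns a tidy
    frame with columns group, bin, mean, sd, n.
    """
    labels = labels.reindex(profiles.index)
    if labels.isna().any():
        missing = list(profiles.index[labels.isna()][:5])
        raise ValueError(f"genes without a group label: {missing}")
    rows = []
    for group, sub in profiles.groupby(labels, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {group!r}")
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        for b in profiles.columns:
            rows.append((group, b, float(mean[b]), float(sd[b]), len(sub)))
    return pd.DataFrame(rows, columns=["group", "bin", "mean", "sd", "n"])


def assign_expression_quartiles(values: pd.Series) -> pd.Series:
    """Split genes into four equal-sized groups by average expression.

    Quartile 1 holds the lowest-expressed genes. Group sizes are
    ``floor(n/4)`` with the remainder distributed to the lowest quartiles;
    ties are broken by stable input order.
    """
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 genes for quartiles")
    order = np.argsort(values.to_numpy(), kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[pos : pos + size]] = q
        pos += size
    return pd.Series(labels, index=values.index, name="expression_quartile")


def ratio_heatmap(
    kd_profiles: pd.DataFrame,
    ctrl_profiles: pd.DataFrame,
    pseudocount: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-bin log2((kd+c)/(ctrl+c)) plus a total-signal channel.

    The ratio matrix is the color channel of a knockdown-vs-control heatmap;
    the returned total signal (kd + ctrl summed over bins) drives opacity.
    """
    if not kd_profiles.index.equals(ctrl_profiles.index):
        raise ValueError("profile matrices must share the gene set")
    ratio = np.log2(kd_profiles + pseudocount) - np.log2(ctrl_profiles + pseudocount)
    total = kd_profiles.sum(axis=1) + ctrl_profiles.sum(axis=1)
    return ratio, total.rename("total_signal")
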