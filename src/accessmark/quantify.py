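"""Region universes, fragment counting and FPKM normalization.

The countable unit is the fragment midpoint: a fragment belongs to the region
containing ``floor((start + end) / 2)``. Over a gap-free window tiling this
rule partitions the library exactly, so per-chromosome counts conserve the
library size; over (possibly overlapping) gene bodies a fragment is assigned
to every region whose span contains the midpoint.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import FragmentSet, Genome, RegionSet, SignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_WIDTH = 10_000
#: loci shorter than this are flagged when building region sets
SHORT_REGION_FLAG_BP = 500


# ---------------------------------------------------------------------------
# region universes


def make_windows(genome: Genome, width: int = DEFAULT_WINDOW_WIDTH) -> RegionSet:
    """Tile every chromosome with consecutive ``width``-bp windows.

    The final partial window is kept; its true length is what FPKM divides by.
    The tiling covers every base exactly once.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    rows = []
    for chrom in genome:
        size = genome[chrom]
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    frame["region_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
    ]
    return RegionSet(frame[["region_id", "chrom", "start", "end"]], kind="window")


def genes_as_regions(annotation: pd.DataFrame) -> RegionSet:
    """Gene bodies as a region set (no flanks), keyed by gene symbol."""
    frame = annotation.rename(columns={"symbol": "region_id"})[
        ["region_id", "chrom", "start", "end", "strand"]
    ].copy()
    n_short = int(((frame["end"] - frame["start"]) < SHORT_REGION_FLAG_BP).sum())
    if n_short:
        logger.info("genes_as_regions: %d loci shorter than %d bp", n_short, SHORT_REGION_FLAG_BP)
    return RegionSet(frame, kind="gene")


def flank_points(
    points: pd.DataFrame,
    genome: Genome,
    upstream: int = 1000,
    downstream: int = 1000,
) -> RegionSet:
    """Expand points (e.g. TSSes) to strand-aware flanked regions.

    A + strand (or unstranded) point ``p`` becomes ``[p-upstream,
    p+downstream)``; on the - strand upstream is 5' of the point so the span
    is ``[p-downstream, p+upstream)``. Flanks are clipped at chromosome edges
    and the true (clipped) length is used downstream.
    """
    if "pos" not in points.columns or "chrom" not in points.columns:
        raise ValueError("points need 'chrom' and 'pos' columns")
    strand = points["strand"] if "strand" in points.columns else pd.Series("+", index=points.index)
    minus = strand.to_numpy() == "-"
    pos = points["pos"].to_numpy(dtype=np.int64)
    start = np.where(minus, pos - downstream, pos - upstream)
    end = np.where(minus, pos + upstream, pos + downstream)
    sizes = points["chrom"].map(lambda c: genome[c]).to_numpy(dtype=np.int64)
    start = np.clip(start, 0, sizes)
    end = np.clip(end, 0, sizes)
    frame = pd.DataFrame(
        {
            "region_id": [f"{c}:{p}" for c, p in zip(points["chrom"], pos)],
            "chrom": points["chrom"].to_numpy(),
            "start": start,
            "end": end,
        }
    )
    return RegionSet(frame, kind="tss_flank")


# ---------------------------------------------------------------------------
# counting


def _count_chrom(regions: pd.DataFrame, mids: np.ndarray) -> np.ndarray:
    """Midpoint counts for the regions of one chromosome."""
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    counts = np.zeros(len(regions), dtype=np.int64)
    if len(mids) == 0 or len(regions) == 0:
        return counts
    if np.all(s[1:] >= e[:-1]):
        # non-overlapping: binary search against the sorted starts
        idx = np.searchsorted(s, mids, side="right") - 1
        valid = idx >= 0
        valid[valid] &= mids[valid] < e[idx[valid]]
        hit = np.bincount(idx[valid], minlength=len(regions))
        counts[order] = hit
    else:
        tree = IntervalTree.from_tuples(
            (int(a), int(b), i) for i, (a, b) in enumerate(zip(starts, ends))
        )
        for m in mids:
            for iv in tree.at(int(m)):
                counts[iv.data] += 1
    return counts


def count_fragments(regions: RegionSet, fragments: FragmentSet) -> pd.Series:
    """Per-region fragment-midpoint counts for one sample.

    Fragments on chromosomes absent from ``regions`` are ignored (and their
    number logged).
    """
    counts = pd.Series(0, index=regions.ids, dtype=np.int64, name=fragments.label)
    mids_by_chrom = {
        chrom: ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        for chrom, grp in fragments.frame.groupby("chrom", sort=False)
    }
    region_chroms = set(regions.frame["chrom"])
    n_ignored = sum(len(m) for c, m in mids_by_chrom.items() if c not in region_chroms)
    if n_ignored:
        logger.info(
            "count_fragments: ignored %d fragments on chromosomes absent from regions",
            n_ignored,
        )
    for chrom, sub in regions.frame.groupby("chrom", sort=False):
        mids = mids_by_chrom.get(chrom)
        if mids is None:
            continue
        counts.iloc[sub.index] = _count_chrom(sub.reset_index(drop=True), np.sort(mids))
    return counts


def count_matrix(regions: RegionSet, fragment_sets: Iterable[FragmentSet]) -> SignalMatrix:
    """Count several samples over one region set into a raw-count matrix."""
    columns, library_sizes = {}, {}
    for fs in fragment_sets:
        if fs.label in columns:
            raise ValueError(f"duplicate sample label {fs.label!r}")
        columns[fs.label] = count_fragments(regions, fs)
        library_sizes[fs.label] = fs.library_size
    values = pd.DataFrame(columns, index=regions.ids)
    return SignalMatrix(values, "count", library_sizes, regions.lengths())


# ---------------------------------------------------------------------------
# FPKM


def fpkm_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Fragments per kilobase of region per million library fragments.

    ``fpkm = count / ((length / 1000) * (library_size / 1e6))``; invariant
    under joint scaling of counts and library size.
    """
    if matrix.value_kind != "count":
        raise ValueError(f"expected raw counts, got {matrix.value_kind!r}")
    if matrix.library_sizes is None or matrix.region_lengths is None:
        raise ValueError("FPKM needs library sizes and region lengths")
    for label, lib in matrix.library_sizes.items():
        if lib <= 0:
            raise ValueError(f"library size for {label!r} must be positive, got {lib}")
    kb = matrix.region_lengths.loc[matrix.values.index].to_numpy(dtype=float) / 1000.0
    out = {}
    for label in matrix.samples:
        millions = matrix.library_sizes[label] / 1e6
        out[label] = matrix.values[label].to_numpy(dtype=float) / (kb * millions)
    values = pd.DataFrame(out, index=matrix.values.index)
    return SignalMatrix(values, "fpkm", dict(matrix.library_sizes), matrix.region_lengths)


def quantify_flanked_points(
    points: pd.DataFrame,
    fragment_sets: Iterable[FragmentSet],
    genome: Genome,
    upstream: int = 1000,
    downstream: int = 1000,
) -> SignalMatrix:
    """FPKM signal in flanked point regions (e.g. TSS +/- 1 kb)."""
    regions = flank_points(points, genome, upstream=upstream, downstream=downstream)
    return fpkm_normalize(count_matrix(regions, fragment_sets))


# ---------------------------------------------------------------------------
# overlap classification and low-signal filtering


def classify_overlap(windows: RegionSet, targets: RegionSet) -> pd.DataFrame:
    """Partition windows by their border distance to the nearest target.

    The border distance of window ``w`` to target ``t`` is
    ``max(t.start - w.end, w.start - t.end)``: negative when the intervals
    intersect, zero when they touch under half-open adjacency, positive
    otherwise. A window is classified overlapping iff its minimum distance
    over same-chromosome targets is <= 0 (touching counts as overlapping).

    Returns a frame indexed by window id with columns ``border_distance``
    (inf where the chromosome has no targets) and ``overlapping``.
    """
    distances = np.full(len(windows), np.inf)
    if len(targets) == 0:
        warnings.warn("classify_overlap: empty target set; all windows non-overlapping")
    else:
        by_chrom = {}
        for chrom, grp in targets.frame.groupby("chrom", sort=False):
            order = np.argsort(grp["start"].to_numpy(), kind="stable")
            s = grp["start"].to_numpy()[order]
            e = grp["end"].to_numpy()[order]
            by_chrom[chrom] = (s, e, np.maximum.accumulate(e))
        for wi, (chrom, w_start, w_end) in enumerate(
            zip(windows.frame["chrom"], windows.frame["start"], windows.frame["end"])
        ):
            if chrom not in by_chrom:
                continue
            s, e, prefix_max_e = by_chrom[chrom]
            i = int(np.searchsorted(s, w_end, side="right"))  # targets with start <= w_end
            best = np.inf
            if i < len(s):
                best = s[i] - w_end
            if i > 0:
                if prefix_max_e[i - 1] >= w_start:
                    # at least one candidate overlaps/touches; scan back for the minimum
                    j = i - 1
                    while j >= 0 and prefix_max_e[j] >= w_start:
                        d = max(s[j] - w_end, w_start - e[j])
                        if d < best:
                            best = d
                        j -= 1
                else:
                    best = min(best, w_start - prefix_max_e[i - 1])
            distances[wi] = best
    out = pd.DataFrame(
        {"border_distance": distances, "overlapping": distances <= 0},
        index=windows.ids,
    )
    return out


def filter_low_signal(
    matrix: SignalMatrix,
    control_samples: Sequence[str],
    min_total_count: int = 10,
) -> tuple[SignalMatrix, list]:
    """Drop regions whose summed control-sample counts fall below a threshold.

    Emulates the exclusion of windows that attract very few or no reads
    because of low mappability. Returns the filtered matrix and the list of
    excluded region ids (persist it so downstream matrices stay aligned).
    """
    if min_total_count < 0:
        raise ValueError("min_total_count must be >= 0")
    if matrix.value_kind != "count":
        raise ValueError("filter_low_signal expects raw counts")
    missing = [s for s in control_samples if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"control samples not in matrix: {missing}")
    totals = matrix.values[list(control_samples)].sum(axis=1)
    keep = totals >= min_total_count
    excluded = list(matrix.values.index[~keep])
    filtered = SignalMatrix(
        matrix.values.loc[keep].copy(),
        matrix.value_kind,
        dict(matrix.library_sizes) if matrix.library_sizes else None,
        None if matrix.region_lengths is None else matrix.region_lengths.loc[keep],
    )
    logger.info("filter_low_signal: excluded %d/%d regions", len(excluded), len(totals))
    return filtered, excluded
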