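"""Readers, writers and coordinate manipulations for the standard formats.

All tabular output is plain TSV; BED output is BED6 with ``name="."`` and
``score=0`` so that sorted files round-trip byte-for-byte. Every reader
transparently accepts gzip-compressed files (by ``.gz`` suffix).
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import replace
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_COLUMNS,
    CoordinateError,
    FragmentSet,
    Genome,
    validate_annotation,
)

logger = logging.getLogger(__name__)

#: number of bases removed from a fragment by the Tn5 end adjustment
TN5_SHIFT_START = 5
TN5_SHIFT_END = 4


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column ``chrom<TAB>size`` file into a genome model."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable size {fields[1]!r}") from exc
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for chrom in genome:
            fh.write(f"{chrom}\t{genome[chrom]}\n")


# ---------------------------------------------------------------------------
# BED fragments


def read_bed(
    path: str | Path,
    genome: Genome | None = None,
    *,
    assay: str = "",
    condition: str = "",
    replicate: int = 0,
    label: str = "",
) -> FragmentSet:
    """Read a BED3+ file into a :class:`FragmentSet`.

    Malformed lines raise with the offending line number; when ``genome`` is
    given, intervals on unknown chromosomes or outside chromosome bounds are
    rejected.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            if not (0 <= start < end):
                raise CoordinateError(
                    f"{path}:{lineno}: invalid coordinate order {start} >= {end}"
                )
            if genome is not None:
                if chrom not in genome:
                    raise CoordinateError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > genome[chrom]:
                    raise CoordinateError(
                        f"{path}:{lineno}: interval end {end} beyond {chrom} "
                        f"length {genome[chrom]}"
                    )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    frame = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
        }
    )
    return FragmentSet(frame, assay=assay, condition=condition, replicate=replicate, label=label)


def write_bed(fragments: FragmentSet, path: str | Path) -> None:
    """Write fragments as sorted BED6 (name ``.``, score ``0``, strand ``.``)."""
    frame = fragments.sorted().frame
    with open(path, "wt") as fh:
        for chrom, start, end in frame.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t.\n")


# ---------------------------------------------------------------------------
# gene annotation


def read_annotation(path: str | Path, *, require_unique: bool = True) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"symbol": str, "chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return validate_annotation(frame, require_unique=require_unique)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def collapse_genes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated gene symbols to single records with outermost coordinates.

    Every record of a symbol must sit on one chromosome and strand; offenders
    are reported by name. Output carries one row per symbol, with
    ``start = min(starts)`` and ``end = max(ends)``, ordered by position.
    """
    annotation = validate_annotation(annotation, require_unique=False)
    if annotation.empty:
        return annotation
    grouped = annotation.groupby("symbol", sort=False)
    n_chrom = grouped["chrom"].nunique()
    n_strand = grouped["strand"].nunique()
    bad = sorted(set(n_chrom[n_chrom > 1].index) | set(n_strand[n_strand > 1].index))
    if bad:
        raise ValueError(
            f"symbols mapped to multiple chromosomes or strands: {bad[:10]}"
        )
    collapsed = grouped.agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        strand=("strand", "first"),
        is_housekeeping=("is_housekeeping", "any"),
    ).reset_index()
    collapsed = collapsed.sort_values(["chrom", "start", "end"], kind="mergesort")
    return validate_annotation(collapsed.reset_index(drop=True))


def extract_tss(annotation: pd.DataFrame) -> pd.DataFrame:
    """Return the unique transcription start sites of an annotation.

    TSS is ``start`` for + strand genes and ``end - 1`` for - strand genes
    (the 5'-most covered base); exact duplicate coordinates are merged.
    Unstranded records are treated as + strand.
    """
    annotation = validate_annotation(annotation)
    if annotation.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    pos = np.where(
        annotation["strand"].to_numpy() == "-",
        annotation["end"].to_numpy() - 1,
        annotation["start"].to_numpy(),
    )
    tss = pd.DataFrame({"chrom": annotation["chrom"], "pos": pos})
    tss = tss.drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    return tss.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tn5 end adjustment


def tn5_adjust(fragments: FragmentSet) -> tuple[FragmentSet, int]:
    """Shift fragment ends by +5/-4 bp to center on Tn5 insertion sites.

    Each interval becomes ``[start+5, end-4)`` and so shrinks by exactly 9 bp;
    fragments of 9 bp or shorter would collapse and are dropped (the count of
    dropped fragments is returned and logged). The operation is deliberately
    not idempotent: applying it twice shrinks fragments by 18 bp.
    """
    frame = fragments.frame
    keep = (frame["end"] - frame["start"]) > (TN5_SHIFT_START + TN5_SHIFT_END)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("tn5_adjust: dropped %d fragments shorter than 10 bp", n_dropped)
    adjusted = frame[keep].copy()
    adjusted["start"] = adjusted["start"] + TN5_SHIFT_START
    adjusted["end"] = adjusted["end"] - TN5_SHIFT_END
    return replace(fragments, frame=adjusted.reset_index(drop=True)), n_dropped


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression table (first column = gene symbol)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="symbol", float_format="%.6g")
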