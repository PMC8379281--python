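"""Core data containers shared across the pipeline.

Coordinates are 0-based, half-open (BED convention) everywhere: an interval
``[start, end)`` covers bases ``start .. end-1``. Strand is one of ``+``,
``-`` or ``.``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

#: column order for fragment tables
FRAGMENT_COLUMNS = ["chrom", "start", "end"]
#: column order for gene annotation tables
ANNOTATION_COLUMNS = ["symbol", "chrom", "start", "end", "strand", "is_housekeeping"]


class CoordinateError(ValueError):
    """A genomic coordinate violates the 0-based half-open convention."""


class CapacityError(RuntimeError):
    """A simulated genome is too small for the requested gene complement."""


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Genome:
    """Chromosome names and lengths (the genome model)."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.sizes.items():
            if size <= 0:
                raise CoordinateError(f"chromosome {chrom} has non-positive size {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes.keys())

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return int(self.sizes[chrom])

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)


def validate_annotation(frame: pd.DataFrame, *, require_unique: bool = True) -> pd.DataFrame:
    """Validate a gene annotation table and return it with canonical dtypes.

    Expected columns: symbol, chrom, start, end, strand, is_housekeeping.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    out = frame[ANNOTATION_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out["is_housekeeping"] = out["is_housekeeping"].astype(bool)
    if len(out):
        bad = out[(out["start"] < 0) | (out["start"] >= out["end"])]
        if len(bad):
            raise CoordinateError(
                f"annotation holds {len(bad)} invalid intervals, first: "
                f"{bad.iloc[0]['symbol']}"
            )
        bad_strand = set(out["strand"]) - set(VALID_STRANDS)
        if bad_strand:
            raise CoordinateError(f"invalid strand values: {sorted(bad_strand)}")
        if require_unique and out["symbol"].duplicated().any():
            dups = out.loc[out["symbol"].duplicated(), "symbol"].unique()[:5]
            raise ValueError(f"duplicate gene symbols (collapse first): {list(dups)}")
    return out


@dataclass
class FragmentSet:
    """A labeled collection of genomic fragments for one sample.

    ``frame`` has columns chrom/start/end; ``library_size`` is simply the
    number of fragments.
    """

    frame: pd.DataFrame
    assay: str = ""
    condition: str = ""
    replicate: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment table is missing columns: {missing}")
        self.frame = self.frame[FRAGMENT_COLUMNS].reset_index(drop=True)
        if not self.label:
            parts = [p for p in (self.assay, self.condition) if p]
            self.label = "_".join(parts) + (f"_r{self.replicate}" if parts else "")

    @property
    def library_size(self) -> int:
        return len(self.frame)

    def midpoints(self) -> pd.DataFrame:
        mids = (self.frame["start"].to_numpy() + self.frame["end"].to_numpy()) // 2
        return pd.DataFrame({"chrom": self.frame["chrom"], "pos": mids})

    def sorted(self) -> "FragmentSet":
        frame = self.frame.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return replace(self, frame=frame)

    def validate_against(self, genome: Genome) -> None:
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            if chrom not in genome:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            if (grp["start"] < 0).any() or (grp["end"] > genome[chrom]).any():
                raise CoordinateError(f"fragment outside bounds of {chrom}")


@dataclass
class RegionSet:
    """An ordered set of uniquely-identified regions of one kind.

    ``frame`` columns: region_id, chrom, start, end (strand optional).
    """

    frame: pd.DataFrame
    kind: str = "window"

    def __post_init__(self) -> None:
        for col in ("region_id", "chrom", "start", "end"):
            if col not in self.frame.columns:
                raise ValueError(f"region table is missing column {col!r}")
        if self.frame["region_id"].duplicated().any():
            raise ValueError("region ids must be unique")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.frame["region_id"])

    def lengths(self) -> pd.Series:
        out = (self.frame["end"] - self.frame["start"]).astype(np.int64)
        out.index = self.frame["region_id"]
        return out

    def subset(self, ids) -> "RegionSet":
        keep = self.frame[self.frame["region_id"].isin(set(ids))]
        return RegionSet(keep.copy(), kind=self.kind)


@dataclass
class SignalMatrix:
    """Regions x samples signal table plus the metadata needed downstream.

    ``value_kind`` is one of count / fpkm / quantile_normalized / log2_ratio.
    """

    values: pd.DataFrame
    value_kind: str
    library_sizes: dict[str, int] | None = None
    region_lengths: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame, value_kind: str | None = None) -> "SignalMatrix":
        return SignalMatrix(
            values=values,
            value_kind=value_kind or self.value_kind,
            library_sizes=dict(self.library_sizes) if self.library_sizes else None,
            region_lengths=None
            if self.region_lengths is None
            else self.region_lengths.loc[values.index],
        )

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="region_id", float_format=float_format)
        meta = {
            "value_kind": self.value_kind,
            "library_sizes": self.library_sizes,
            "region_lengths": None
            if self.region_lengths is None
            else {str(k): int(v) for k, v in self.region_lengths.items()},
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=0, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="region_id")
        meta_path = Path(str(path) + ".meta.json")
        value_kind, library_sizes, region_lengths = "count", None, None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            value_kind = meta.get("value_kind", "count")
            library_sizes = meta.get("library_sizes")
            rl = meta.get("region_lengths")
            if rl is not None:
                region_lengths = pd.Series(rl)
                region_lengths.index.name = "region_id"
                region_lengths = region_lengths.loc[values.index.astype(str)]
                region_lengths.index = values.index
        return cls(values, value_kind, library_sizes, region_lengths)
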