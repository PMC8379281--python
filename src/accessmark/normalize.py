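"""Quantile normalization, replicate averaging, log-ratio contrasts and
binned 2D statistics.

These are the operations that turn per-region FPKM tables into the
comparisons of the analysis: ChIP enrichment over the histone H4 control,
MA contrasts of knockdown vs control accessibility, per-gene Pearson
correlations and 2D-histogram summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.1  # FPKM units

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log2": np.log2,
    "log10": np.log10,
    "identity": lambda x: x,
}


def _as_transform(t) -> Callable[[np.ndarray], np.ndarray]:
    if t is None:
        return _TRANSFORMS["identity"]
    if callable(t):
        return t
    try:
        return _TRANSFORMS[t]
    except KeyError:
        raise ValueError(f"unknown transform {t!r}; use one of {sorted(_TRANSFORMS)}")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to their common per-rank mean distribution.

    The reference distribution is the per-rank mean of the sorted columns;
    each value is replaced by the reference value at its within-column rank.
    Tied values receive the mean of their tied ranks' reference values, so
    an all-constant column collapses to the reference mean.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = values.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average reference values over tied input values
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
        if np.all(col == col[0]):
            logger.info(
                "quantile_normalize: column %r is constant; set to reference mean",
                values.columns[j],
            )
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def average_replicates(
    values: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean per region per condition.

    ``grouping`` maps every sample column to its condition; conditions appear
    in the output in order of first appearance.
    """
    missing = [c for c in values.columns if c not in grouping]
    if missing:
        raise ValueError(f"samples without a condition assignment: {missing}")
    conditions: list[str] = []
    for sample in values.columns:
        cond = grouping[sample]
        if cond not in conditions:
            conditions.append(cond)
    out = {}
    for cond in conditions:
        cols = [s for s in values.columns if grouping[s] == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} has no samples")
        out[cond] = values[cols].mean(axis=1)
    return pd.DataFrame(out, index=values.index)


# ---------------------------------------------------------------------------
# log-ratio contrasts


def log2_enrichment(
    chip, control, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Per-region ``log2((chip + c) / (control + c))`` ChIP enrichment."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    chip = pd.Series(chip, dtype=float)
    control = pd.Series(control, dtype=float)
    if not chip.index.equals(control.index):
        raise ValueError("chip and control must share a region set")
    return np.log2(chip + pseudocount) - np.log2(control + pseudocount)


def ma_transform(
    kd, ctrl, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """MA contrast of knockdown over control signal.

    ``M = log2(kd/ctrl)`` and ``A = 0.5 * log2(kd * ctrl)`` on the
    pseudocounted values; invertible via ``kd = 2**(A + M/2)`` and
    ``ctrl = 2**(A - M/2)``.
    """
    kd = pd.Series(kd, dtype=float) + pseudocount
    ctrl = pd.Series(ctrl, dtype=float) + pseudocount
    if not kd.index.equals(ctrl.index):
        raise ValueError("kd and ctrl must share a region set")
    if (kd <= 0).any() or (ctrl <= 0).any():
        raise ValueError("non-positive values after pseudocount")
    lk, lc = np.log2(kd), np.log2(ctrl)
    return pd.DataFrame({"M": lk - lc, "A": 0.5 * (lk + lc)}, index=kd.index)


def ma_invert(ma: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Recover the (pseudocounted) kd and ctrl signals from an MA frame."""
    kd = np.power(2.0, ma["A"] + ma["M"] / 2.0)
    ctrl = np.power(2.0, ma["A"] - ma["M"] / 2.0)
    return kd, ctrl


# ---------------------------------------------------------------------------
# correlation


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation on unbinned per-region values.

    Non-finite pairs are dropped pairwise (and their number logged). With
    fewer than 3 finite pairs, or zero variance in either vector, the
    correlation is undefined and ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    finite = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("pearson_r: dropped %d non-finite pairs", n_dropped)
    x, y = x[finite], y[finite]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# binned 2D statistics


@dataclass
class Hist2D:
    """A 2D histogram with an optional per-bin mean color channel.

    ``counts[i, j]`` is the number of points in x-bin ``i`` and y-bin ``j``;
    ``color_mean`` is defined (non-NaN) only where ``count > 0``. The count
    channel drives opacity in the three-way plots; the color channel carries
    e.g. mean ChIP enrichment.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    color_mean: np.ndarray | None = None
    n_dropped: int = 0
    x_transform: str = "identity"
    y_transform: str = "identity"

    def to_text(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"# hist2d n_bins_x={len(self.x_edges) - 1} "
                     f"n_bins_y={len(self.y_edges) - 1} n_dropped={self.n_dropped} "
                     f"x_transform={self.x_transform} y_transform={self.y_transform} "
                     f"has_color={int(self.color_mean is not None)}\n")
            np.savetxt(fh, self.x_edges[None, :], fmt="%.8g", delimiter="\t")
            np.savetxt(fh, self.y_edges[None, :], fmt="%.8g", delimiter="\t")
            np.savetxt(fh, self.counts, fmt="%d", delimiter="\t")
            if self.color_mean is not None:
                np.savetxt(fh, self.color_mean, fmt="%.8g", delimiter="\t")

    @classmethod
    def from_text(cls, path: str | Path) -> "Hist2D":
        lines = Path(path).read_text().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split() if "=" in kv)
        nx, ny = int(header["n_bins_x"]), int(header["n_bins_y"])
        x_edges = np.fromstring(lines[1], sep="\t")
        y_edges = np.fromstring(lines[2], sep="\t")
        counts = np.loadtxt(lines[3 : 3 + nx], delimiter="\t", ndmin=2).astype(np.int64)
        color = None
        if int(header.get("has_color", "0")):
            color = np.loadtxt(lines[3 + nx : 3 + 2 * nx], delimiter="\t", ndmin=2)
        return cls(
            x_edges, y_edges, counts, color, int(header.get("n_dropped", "0")),
            header.get("x_transform", "identity"), header.get("y_transform", "identity"),
        )


def hist2d_stats(
    x,
    y,
    color=None,
    n_bins: int = 100,
    x_transform=None,
    y_transform=None,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> Hist2D:
    """Equal-width 2D binning with counts and optional per-bin mean color.

    Axes are binned on the transformed scale over the observed (or supplied)
    range; non-finite points (e.g. log of zero) are dropped and counted.
    Counts always sum to the number of finite input points.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tx, ty = _as_transform(x_transform), _as_transform(y_transform)
    with np.errstate(divide="ignore", invalid="ignore"):
        xv = tx(np.asarray(x, dtype=float))
        yv = ty(np.asarray(y, dtype=float))
    cv = None if color is None else np.asarray(color, dtype=float)
    finite = np.isfinite(xv) & np.isfinite(yv)
    if cv is not None:
        finite &= np.isfinite(cv)
        cv = cv[finite]
    n_dropped = int((~finite).sum())
    xv, yv = xv[finite], yv[finite]
    bins_range = None
    if x_range is not None or y_range is not None:
        bins_range = (
            x_range or (xv.min(), xv.max()),
            y_range or (yv.min(), yv.max()),
        )
    counts, x_edges, y_edges = np.histogram2d(xv, yv, bins=n_bins, range=bins_range)
    color_mean = None
    if cv is not None:
        sums, _, _, _ = stats.binned_statistic_2d(
            xv, yv, cv, statistic="sum", bins=[x_edges, y_edges]
        )
        with np.errstate(invalid="ignore"):
            color_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    name = lambda t: t if isinstance(t, str) else ("identity" if t is None else "custom")
    return Hist2D(
        x_edges, y_edges, counts.astype(np.int64), color_mean, n_dropped,
        name(x_transform), name(y_transform),
    )


def render_hist2d(hist: Hist2D, path: str | Path, cmap: str = "viridis") -> None:
    """Optional PNG heatmap of a :class:`Hist2D` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    grid = hist.color_mean if hist.color_mean is not None else hist.counts
    mesh = ax.pcolormesh(hist.x_edges, hist.y_edges, grid.T, cmap=cmap)
    fig.colorbar(mesh, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
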