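"""k-means clustering of intragenic histone-mark profiles and the
cluster-vs-differential-expression enrichment statistic.

The clustering operates on untransformed gene-body FPKM bin profiles
concatenated across tracks (conditions/timepoints). A deterministic Lloyd
k-means with greedy farthest-point seeding is used so a seed fully
reproduces the partition; cluster ids are relabeled by descending mean total
signal, so cluster 1 always carries the strongest profiles.

Differential expression between knockdown and control uses a per-gene Welch
t-test with Benjamini-Hochberg correction — a deliberately simple stand-in
for a moderated linear-model analysis; the enrichment machinery accepts any
externally produced table with the same columns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FragmentSet, Genome
from .metagene import profile_matrix

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_RESTARTS = 10
DEFAULT_FEATURE_BINS = 20
MAX_LLOYD_ITER = 300


# ---------------------------------------------------------------------------
# features


def build_profile_features(
    annotation: pd.DataFrame,
    tracks: Mapping[str, FragmentSet],
    genome: Genome,
    track_order: Sequence[str] | None = None,
    n_bins: int = DEFAULT_FEATURE_BINS,
) -> pd.DataFrame:
    """Per-gene concatenated body-bin FPKM features across tracks.

    Gene bodies only (no flanks) and no log transformation. Feature columns
    are named ``<track>:b<i>``; row order follows the annotation.
    """
    if track_order is None:
        track_order = list(tracks)
    missing = [t for t in track_order if t not in tracks]
    if missing:
        raise ValueError(f"missing tracks: {missing}")
    blocks = []
    for name in track_order:
        mat = profile_matrix(
            tracks[name], annotation, genome,
            n_body_bins=n_bins, n_flank_bins=0, scale="fpkm",
        )
        mat.columns = [f"{name}:{c}" for c in mat.columns]
        blocks.append(mat)
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# k-means


@dataclass
class ClusterResult:
    """Gene labels (1..k), centroids, and the within-cluster sum of squares."""

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float
    seed: int
    n_restarts: int

    @property
    def k(self) -> int:
        return len(self.centroids)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _farthest_point_seed(X: np.ndarray, k: int, first: int) -> np.ndarray:
    """Greedy farthest-point seeding from a given first center."""
    n = X.shape[0]
    centers = [first % n]
    d2 = np.sum((X - X[centers[0]]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))  # ties -> lowest index
        centers.append(nxt)
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    return X[centers].copy()


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the worst-fit point
                worst = int(np.argmax(d2[np.arange(len(X)), new_labels]))
                centers[c] = X[worst]
                new_labels[worst] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, inertia


def kmeans_profiles(
    features: pd.DataFrame,
    k: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    standardize: bool = False,
    max_iter: int = MAX_LLOYD_ITER,
) -> ClusterResult:
    """Deterministic restarted Lloyd k-means on profile features.

    The best (lowest within-cluster sum of squares) of ``n_restarts`` runs is
    kept. Features are used raw by default (``standardize=True`` z-scores
    columns first). Cluster ids are relabeled 1..k by descending centroid
    total signal for stable reporting.
    """
    X = features.to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} must be in 1..{n_distinct} (distinct rows)")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    master = np.random.default_rng(seed)
    base = int(master.integers(X.shape[0]))
    n = X.shape[0]
    if k == 2 and n <= 32:
        # tiny two-cluster problems: seed from every point pair, which in
        # practice recovers the exhaustive-search optimum
        seedings = [X[[i, j]].copy() for i in range(n) for j in range(i + 1, n)]
    else:
        # restarts walk distinct first centers for seeding diversity
        seedings = [
            _farthest_point_seed(X, k, base + r) for r in range(max(1, n_restarts))
        ]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for centers in seedings:
        labels, centers, inertia = _lloyd(X, centers, max_iter)
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers)
    inertia, labels, centers = best
    # relabel by descending mean total signal of the original-scale centroids
    raw = features.to_numpy(dtype=float)
    totals = np.array([raw[labels == c].mean(axis=0).sum() if (labels == c).any() else -np.inf
                       for c in range(k)])
    order = np.argsort(-totals, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[labels]
    centroids = pd.DataFrame(
        centers[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=features.columns,
    )
    return ClusterResult(
        labels=pd.Series(new_labels, index=features.index, name="cluster"),
        centroids=centroids,
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# stand-in differential expression


def de_test_standin(
    expression: pd.DataFrame,
    grouping: Mapping[str, str],
    ctrl: str = "ctrl",
    kd: str = "set8kd",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of log2 expression, BH-corrected.

    ``expression`` holds log2 values (genes x samples); ``grouping`` maps
    sample columns to conditions. Direction is the sign of the kd - ctrl
    mean difference where the BH-adjusted p is below ``alpha``, else ``ns``.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    ctrl_cols = [s for s in expression.columns if grouping.get(s) == ctrl]
    kd_cols = [s for s in expression.columns if grouping.get(s) == kd]
    if len(ctrl_cols) < 2 or len(kd_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for the Welch test")
    a = expression[kd_cols].to_numpy(dtype=float)
    b = expression[ctrl_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    padj = bh_adjust(p)
    direction = np.where(
        padj < alpha, np.where(diff > 0, "up", "down"), "ns"
    )
    direction = np.where((padj < alpha) & (diff == 0), "ns", direction)
    return pd.DataFrame(
        {"log2fc": diff, "p": p, "padj": padj, "direction": direction},
        index=expression.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cluster x DE enrichment


def cluster_de_enrichment(
    clusters: ClusterResult | pd.Series,
    de: pd.DataFrame,
    directions: Sequence[str] = ("up", "down"),
) -> pd.DataFrame:
    """Observed vs expected significant genes per cluster and direction.

    For each cluster x direction the observed count of significant genes is
    compared with ``cluster size x global direction frequency``; the test is
    a Pearson chi-square (no continuity correction) on the 2x2 table
    [in-cluster: direction vs not | out-of-cluster: direction vs not], with
    BH correction across all cluster x direction tests. The reported log2
    fold uses a Haldane 0.5 offset to stay finite; raw observed/expected
    counts are also emitted. Rows with expected < 1 are flagged
    ``low_expected``; a direction with no significant genes anywhere gets
    p = 1 and flag ``empty_direction``.
    """
    labels = clusters.labels if isinstance(clusters, ClusterResult) else clusters
    if not labels.index.equals(de.index):
        common = labels.index.intersection(de.index)
        if len(common) != len(labels) or len(common) != len(de):
            raise ValueError("clusters and DE calls must cover the same gene universe")
        de = de.loc[labels.index]
    n_total = len(labels)
    rows = []
    for cluster_id in sorted(labels.unique()):
        in_cluster = labels == cluster_id
        size = int(in_cluster.sum())
        for direction in directions:
            is_dir = (de["direction"] == direction).to_numpy()
            dir_total = int(is_dir.sum())
            observed = int((is_dir & in_cluster.to_numpy()).sum())
            expected = size * dir_total / n_total
            flag = ""
            if dir_total == 0:
                chi2, pval = 0.0, 1.0
                flag = "empty_direction"
            else:
                table = np.array(
                    [
                        [observed, size - observed],
                        [dir_total - observed, (n_total - size) - (dir_total - observed)],
                    ],
                    dtype=float,
                )
                if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                    chi2, pval = 0.0, 1.0
                    flag = "degenerate_table"
                else:
                    chi2, pval, _, _ = stats.chi2_contingency(table, correction=False)
                if expected < 1 and not flag:
                    flag = "low_expected"
            rows.append(
                (
                    cluster_id, direction, size, observed, expected,
                    float(np.log2((observed + 0.5) / (expected + 0.5))),
                    float(chi2), float(pval), flag,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster", "direction", "cluster_size", "observed", "expected",
            "log2_fold", "chi2", "p", "flag",
        ],
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["neg_log10_padj"] = -np.log10(np.maximum(out["padj"], 1e-300))
    return out[
        [
            "cluster", "direction", "cluster_size", "observed", "expected",
            "log2_fold", "chi2", "p", "padj", "neg_log10_padj", "flag",
        ]
    ]
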