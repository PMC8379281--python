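import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from accessmark.cluster import (
    bh_adjust,
    build_profile_features,
    cluster_de_enrichment,
    de_test_standin,
    kmeans_profiles,
)
from accessmark.core import Genome
from accessmark.metagene import profile_matrix
from conftest import make_fragments


# ---------------------------------------------------------------------------
# oracles


def exhaustive_kmeans_2(X):
    """Best 2-partition objective by enumerating all assignments (n <= 12)."""
    n = len(X)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        bits = np.array(bits)
        if bits.sum() in (0, n):
            continue
        obj = 0.0
        for c in (0, 1):
            sub = X[bits == c]
            obj += ((sub - sub.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


def bh_oracle(p):
    """Quadratic-time min-over-suffix Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j for j in range(rank_pos, n + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


# ---------------------------------------------------------------------------
# features


class TestBuildProfileFeatures:
    GENOME = Genome({"chr1": 50_000})

    def _annotation(self):
        return pd.DataFrame(
            {
                "symbol": ["A", "B"],
                "chrom": ["chr1", "chr1"],
                "start": [1000, 9000],
                "end": [3000, 10_000],
                "strand": ["+", "-"],
                "is_housekeeping": [False, True],
            }
        )

    def _tracks(self):
        rng = np.random.default_rng(0)
        out = {}
        for name in ("t1", "t2"):
            starts = rng.integers(500, 10_500, 300)
            out[name] = make_fragments(
                [("chr1", int(s), int(s) + 60) for s in starts], label=name
            )
        return out

    def test_shape_two_tracks_times_bins(self):
        feats = build_profile_features(
            self._annotation(), self._tracks(), self.GENOME, n_bins=20
        )
        assert feats.shape == (2, 40)

    def test_missing_track_named(self):
        with pytest.raises(ValueError, match="t3"):
            build_profile_features(
                self._annotation(), self._tracks(), self.GENOME,
                track_order=["t1", "t3"],
            )

    def test_rows_equal_flankless_metagene_bins(self):
        ann, tracks = self._annotation(), self._tracks()
        feats = build_profile_features(ann, tracks, self.GENOME,
                                       track_order=["t1"], n_bins=20)
        mat = profile_matrix(tracks["t1"], ann, self.GENOME,
                             n_body_bins=20, n_flank_bins=0)
        np.testing.assert_allclose(feats.to_numpy(), mat.to_numpy())


# ---------------------------------------------------------------------------
# k-means


class TestKmeans:
    def _frame(self, X):
        return pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))])

    def test_separated_pairs_partitioned(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        res = kmeans_profiles(self._frame(X), k=2, n_restarts=4, seed=0)
        labels = res.labels.to_numpy()
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        # high-signal pair relabeled as cluster 1
        assert labels[2] == 1

    def test_k1_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        res = kmeans_profiles(self._frame(X), k=1, n_restarts=2, seed=0)
        np.testing.assert_allclose(res.centroids.iloc[0].to_numpy(), X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_duplicated_rows_double_objective(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 2))
        single = kmeans_profiles(self._frame(X), k=2, n_restarts=8, seed=3)
        doubled = kmeans_profiles(
            pd.DataFrame(np.vstack([X, X])), k=2, n_restarts=8, seed=3
        )
        assert doubled.inertia == pytest.approx(2 * single.inertia, rel=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = self._frame(rng.normal(size=(40, 4)))
        a = kmeans_profiles(X, k=3, seed=9)
        b = kmeans_profiles(X, k=3, seed=9)
        pd.testing.assert_series_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_matches_exhaustive_search_on_small_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2))
            res = kmeans_profiles(self._frame(X), k=2, n_restarts=10, seed=0)
            assert res.inertia == pytest.approx(exhaustive_kmeans_2(X), rel=1e-9)

    def test_k_above_distinct_rows_rejected(self):
        X = self._frame(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            kmeans_profiles(X, k=2, seed=0)


# ---------------------------------------------------------------------------
# DE stand-in and BH


class TestDeStandin:
    def _expr(self, ctrl, kd):
        frame = pd.DataFrame(
            np.column_stack([ctrl, kd]),
            columns=[f"ctrl_r{i}" for i in range(1, ctrl.shape[1] + 1)]
            + [f"set8kd_r{i}" for i in range(1, kd.shape[1] + 1)],
        )
        grouping = {c: ("set8kd" if c.startswith("set8kd") else "ctrl")
                    for c in frame.columns}
        return frame, grouping

    def test_equal_means_not_significant(self):
        rng = np.random.default_rng(0)
        expr, grouping = self._expr(rng.normal(5, 1, (50, 3)), rng.normal(5, 1, (50, 3)))
        de = de_test_standin(expr, grouping)
        assert (de["direction"] == "ns").mean() > 0.9

    def test_strong_shift_called_down(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(8, 0.1, (100, 4))
        kd = rng.normal(5, 0.1, (100, 4))
        de = de_test_standin(*self._expr(ctrl, kd))
        assert (de["direction"] == "down").all()
        assert (de["log2fc"] < 0).all()

    def test_zero_variance_equal_means_p_one(self):
        expr, grouping = self._expr(np.full((3, 2), 4.0), np.full((3, 2), 4.0))
        de = de_test_standin(expr, grouping)
        assert (de["p"] == 1.0).all()

    def test_single_replicate_rejected(self):
        expr, grouping = self._expr(np.zeros((3, 1)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            de_test_standin(expr, grouping)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_min_over_suffix_oracle(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# enrichment bubbles


class TestClusterDeEnrichment:
    def _setup(self, labels, directions):
        idx = pd.Index([f"g{i}" for i in range(len(labels))], name="symbol")
        lab = pd.Series(labels, index=idx, name="cluster")
        de = pd.DataFrame({"direction": directions}, index=idx)
        return lab, de

    def test_hand_computed_two_by_two(self):
        # 100 genes, cluster of 20, 10 globally up of which 8 in the cluster
        labels = [1] * 20 + [2] * 80
        directions = ["up"] * 8 + ["ns"] * 12 + ["up"] * 2 + ["ns"] * 78
        lab, de = self._setup(labels, directions)
        out = cluster_de_enrichment(lab, de)
        row = out[(out["cluster"] == 1) & (out["direction"] == "up")].iloc[0]
        assert row["observed"] == 8
        assert row["expected"] == pytest.approx(2.0)
        chi2, p, _, _ = stats.chi2_contingency(
            [[8, 12], [2, 78]], correction=False
        )
        assert row["chi2"] == pytest.approx(chi2)
        assert row["p"] == pytest.approx(p)
        assert row["log2_fold"] == pytest.approx(np.log2(8.5 / 2.5))

    def test_observed_equal_expected_null(self):
        labels = [1] * 50 + [2] * 50
        directions = (["up"] * 5 + ["ns"] * 45) * 2
        lab, de = self._setup(labels, directions)
        out = cluster_de_enrichment(lab, de)
        up1 = out[(out["cluster"] == 1) & (out["direction"] == "up")].iloc[0]
        assert up1["chi2"] == pytest.approx(0.0)
        assert up1["p"] == pytest.approx(1.0)
        assert abs(up1["log2_fold"]) < 1e-12

    def test_empty_direction_flagged_p_one(self):
        lab, de = self._setup([1] * 5 + [2] * 5, ["ns"] * 10)
        out = cluster_de_enrichment(lab, de)
        down = out[out["direction"] == "down"]
        assert (down["p"] == 1.0).all()
        assert (down["flag"] == "empty_direction").all()

    def test_observed_sums_to_total_per_direction(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 6, 300)
        directions = rng.choice(["up", "down", "ns"], 300, p=[0.2, 0.3, 0.5])
        lab, de = self._setup(labels, directions)
        out = cluster_de_enrichment(lab, de)
        for direction in ("up", "down"):
            total = (de["direction"] == direction).sum()
            assert out[out["direction"] == direction]["observed"].sum() == total
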