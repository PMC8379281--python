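import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from accessmark import (
    SimulationConfig,
    apply_knockdown,
    simulate_expression,
    simulate_fragments,
    simulate_genome,
    simulate_truth,
)
from accessmark.core import CapacityError


class TestSimulateGenome:
    def test_empty_annotation_for_zero_genes(self):
        cfg = SimulationConfig(n_genes=0)
        genome, ann = simulate_genome(cfg)
        assert len(ann) == 0
        assert genome.total_length == cfg.n_chromosomes * cfg.chromosome_length

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(
            n_chromosomes=1, chromosome_length=1_000_000, n_genes=50,
            gene_length_log_mean=math.log(5000), seed=7,
        )
        _, a = simulate_genome(cfg)
        _, b = simulate_genome(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_genes_unique_nonoverlapping_and_hk_fraction(self):
        cfg = SimulationConfig(seed=2)
        _, ann = simulate_genome(cfg)
        assert ann["symbol"].is_unique
        assert ann["is_housekeeping"].sum() == round(cfg.hk_fraction * cfg.n_genes)
        for _, sub in ann.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_median_gene_length_near_target(self):
        # log-mean corresponds to a 20 kb median; realized median within 10%
        cfg = SimulationConfig(n_genes=2000, gene_length_log_mean=math.log(20_000), seed=1)
        _, ann = simulate_genome(cfg)
        median = float((ann["end"] - ann["start"]).median())
        assert abs(median - 20_000) / 20_000 < 0.10

    def test_capacity_error_when_genome_too_small(self):
        # expected total gene length (250 kb) passes the config check but the
        # genes plus mandatory gaps (250,051 bp) cannot fit in 250,020 bp
        cfg = SimulationConfig(
            n_chromosomes=1, chromosome_length=250_020, n_genes=50,
            gene_length_log_mean=math.log(5000), gene_length_log_sd=0.0, seed=0,
        )
        with pytest.raises(CapacityError):
            simulate_genome(cfg)


class TestSimulateTruth:
    def _truth(self, **kw):
        cfg = SimulationConfig(seed=kw.pop("seed", 1), **kw)
        _, ann = simulate_genome(cfg)
        return simulate_truth(ann, cfg), cfg

    def test_zero_coupling_gives_independence(self):
        truth, _ = self._truth(rho_me1_acc=0.0)
        r = stats.pearsonr(
            np.log2(truth.table["me1_ctrl"]), np.log2(truth.table["acc_ctrl"])
        )[0]
        assert abs(r) < 0.05

    def test_target_coupling_recovered_across_seeds(self):
        rs = []
        for seed in range(1, 6):
            truth, _ = self._truth(seed=seed, rho_me1_acc=0.6)
            rs.append(
                stats.pearsonr(
                    np.log2(truth.table["me1_ctrl"]), np.log2(truth.table["acc_ctrl"])
                )[0]
            )
        assert abs(np.mean(rs) - 0.6) < 0.08

    def test_hk_boost_in_log2_units(self):
        truth, _ = self._truth(hk_me1_boost=2.0, short_gene_me1_slope=0.0)
        log2me1 = np.log2(truth.table["me1_ctrl"])
        hk = truth.table["is_housekeeping"]
        diff = log2me1[hk].mean() - log2me1[~hk].mean()
        assert abs(diff - 2.0) < 0.15

    def test_me3_anticorrelated_with_accessibility(self):
        truth, _ = self._truth(me3_anticorr=-0.5)
        r = stats.pearsonr(
            np.log2(truth.table["me3"]), np.log2(truth.table["acc_ctrl"])
        )[0]
        assert r < -0.3

    def test_invalid_rho_rejected(self):
        cfg = SimulationConfig(rho_me1_acc=1.5)
        _, ann = simulate_genome(SimulationConfig(seed=1))
        with pytest.raises(ValueError):
            simulate_truth(ann, cfg)

    def test_all_latents_strictly_positive(self, tiny_world):
        _, _, truth = tiny_world
        for col in ("me1_ctrl", "me3", "acc_ctrl", "expr_ctrl"):
            assert (truth.table[col] > 0).all()


class TestApplyKnockdown:
    def test_null_effect_leaves_accessibility_identical(self):
        cfg = SimulationConfig(seed=1, kd_acc_effect=0.0)
        _, ann = simulate_genome(cfg)
        truth = apply_knockdown(simulate_truth(ann, cfg), cfg)
        pd.testing.assert_series_equal(
            truth.table["acc_set8kd"], truth.table["acc_ctrl"], check_names=False
        )

    def test_me1_residual_exact_scaling(self):
        cfg = SimulationConfig(seed=1, kd_me1_residual=0.1)
        _, ann = simulate_genome(cfg)
        truth = apply_knockdown(simulate_truth(ann, cfg), cfg)
        np.testing.assert_allclose(
            truth.table["me1_set8kd"], 0.1 * truth.table["me1_ctrl"], rtol=1e-12
        )

    def test_reduction_tracks_me1_rank_weight(self):
        cfg = SimulationConfig(seed=1, kd_acc_effect=0.6)
        _, ann = simulate_genome(cfg)
        truth = apply_knockdown(simulate_truth(ann, cfg), cfg)
        rel_loss = (
            truth.table["acc_ctrl"] - truth.table["acc_set8kd"]
        ) / truth.table["acc_ctrl"]
        rho = stats.spearmanr(truth.table["me1_weight"], rel_loss)[0]
        assert rho >= 0.95

    def test_monotone_in_effect_size(self):
        accs = []
        for effect in (0.0, 0.3, 0.6):
            cfg = SimulationConfig(seed=1, kd_acc_effect=effect)
            _, ann = simulate_genome(cfg)
            truth = apply_knockdown(simulate_truth(ann, cfg), cfg)
            accs.append(truth.table["acc_set8kd"].to_numpy())
        assert (accs[1] <= accs[0]).all() and (accs[2] <= accs[1]).all()


class TestSimulateFragments:
    def test_zero_depth_gives_empty_set_with_metadata(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        cfg = SimulationConfig(**{**tiny_config.__dict__, "depth": 0})
        fs = simulate_fragments(truth, ann, genome, "atac", "ctrl", 1, cfg)
        assert fs.library_size == 0
        assert fs.assay == "atac" and fs.condition == "ctrl"

    def test_same_seed_identical_output(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        a = simulate_fragments(truth, ann, genome, "me1", "ctrl", 1, tiny_config)
        b = simulate_fragments(truth, ann, genome, "me1", "ctrl", 1, tiny_config)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_replicates_differ(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        a = simulate_fragments(truth, ann, genome, "atac", "ctrl", 1, tiny_config)
        b = simulate_fragments(truth, ann, genome, "atac", "ctrl", 2, tiny_config)
        assert not a.frame.equals(b.frame)

    def test_count_conservation(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        fs, counts = simulate_fragments(
            truth, ann, genome, "atac", "ctrl", 1, tiny_config, return_counts=True
        )
        assert fs.library_size == counts.sum()

    def test_unknown_assay_rejected(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        with pytest.raises(ValueError, match="assay"):
            simulate_fragments(truth, ann, genome, "rna", "ctrl", 1, tiny_config)

    def test_poisson_mean_matches_expectation(self):
        # single gene dominating a small genome; nb_dispersion=0 -> Poisson
        cfg = SimulationConfig(
            n_chromosomes=1, chromosome_length=200_000, n_genes=1,
            gene_length_log_mean=math.log(100_000), gene_length_log_sd=0.01,
            depth=120, nb_dispersion=0.0, atac_background=0.0, seed=0,
        )
        genome, ann = simulate_genome(cfg)
        truth = apply_knockdown(simulate_truth(ann, cfg), cfg)
        means = []
        for rep in range(1, 301):
            _, counts = simulate_fragments(
                truth, ann, genome, "atac", "ctrl", rep, cfg, return_counts=True
            )
            means.append(counts.iloc[0])
        # all weight on the single gene -> expected count = depth
        se = math.sqrt(cfg.depth / len(means))
        assert abs(np.mean(means) - cfg.depth) < 3 * se

    def test_fragments_sorted_and_within_bounds(self, tiny_world, tiny_config):
        genome, ann, truth = tiny_world
        fs = simulate_fragments(truth, ann, genome, "me3", "ctrl", 1, tiny_config)
        frame = fs.frame
        assert (frame["start"] < frame["end"]).all()
        assert frame["start"].min() >= 0
        assert frame["end"].max() <= genome["chr1"]
        assert frame.equals(fs.sorted().frame)


class TestSimulateExpression:
    def test_shape_and_determinism(self, tiny_world, tiny_config):
        _, _, truth = tiny_world
        a = simulate_expression(truth, tiny_config)
        b = simulate_expression(truth, tiny_config)
        assert a.shape == (len(truth.table), 2 * tiny_config.n_replicates)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_makes_replicates_identical(self, tiny_world, tiny_config):
        _, _, truth = tiny_world
        cfg = SimulationConfig(**{**tiny_config.__dict__, "expr_noise_sd": 0.0})
        expr = simulate_expression(truth, cfg)
        assert expr["ctrl_r1"].equals(expr["ctrl_r2"])

    def test_column_order_ctrl_then_kd(self, tiny_world, tiny_config):
        _, _, truth = tiny_world
        expr = simulate_expression(truth, tiny_config)
        n = tiny_config.n_replicates
        assert all(c.startswith("ctrl") for c in expr.columns[:n])
        assert all(c.startswith("set8kd") for c in expr.columns[n:])
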