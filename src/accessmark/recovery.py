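"""Synthetic-recovery experiments: run the full pipeline on generated data
and measure whether the analysis recovers the structure the generator
planted.

These are the package's end-to-end self-checks: the generator draws data
with a known coupling between H4K20me1 enrichment, accessibility and
expression, and each function here re-estimates that structure through the
same quantification/normalization path the real analysis would use.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cluster as cl
from . import normalize, quantify
from .synth import (
    SimulationConfig,
    apply_knockdown,
    simulate_expression,
    simulate_fragments,
    simulate_genome,
    simulate_truth,
)

DEFAULT_PSEUDOCOUNT = 0.1


def _world(config: SimulationConfig):
    genome, annotation = simulate_genome(config)
    truth = apply_knockdown(simulate_truth(annotation, config), config)
    return genome, annotation, truth


def _expression_grouping(expression: pd.DataFrame) -> dict[str, str]:
    return {c: ("set8kd" if c.startswith("set8kd") else "ctrl")
            for c in expression.columns}


def gene_level_correlation(config: SimulationConfig) -> float:
    """Per-gene Pearson r of H4K20me1 enrichment vs log10 mean ATAC FPKM.

    The estimate runs the full measurement path: fragment simulation,
    gene-body midpoint counting, FPKM, log2 enrichment over the H4 control,
    replicate-averaged ATAC signal.
    """
    genome, annotation, truth = _world(config)
    reps = range(1, config.n_replicates + 1)
    fsets = [
        simulate_fragments(truth, annotation, genome, "me1", "ctrl", 1, config),
        simulate_fragments(truth, annotation, genome, "h4", "ctrl", 1, config),
    ] + [
        simulate_fragments(truth, annotation, genome, "atac", "ctrl", r, config)
        for r in reps
    ]
    genes = quantify.genes_as_regions(annotation)
    fpkm = quantify.fpkm_normalize(quantify.count_matrix(genes, fsets))
    enrichment = normalize.log2_enrichment(
        fpkm.values["me1_ctrl_r1"], fpkm.values["h4_ctrl_r1"],
        pseudocount=DEFAULT_PSEUDOCOUNT,
    )
    atac_mean = fpkm.values[[f"atac_ctrl_r{r}" for r in reps]].mean(axis=1)
    r, _ = normalize.pearson_r(
        enrichment, np.log10(atac_mean + DEFAULT_PSEUDOCOUNT)
    )
    return r


def window_ma_quartile_gap(config: SimulationConfig, min_total_count: int = 10) -> dict:
    """MA geometry of knockdown accessibility in genic vs intergenic windows.

    Quantifies ATAC in 10 kbp windows, quantile-normalizes across all
    replicates of both conditions, averages per condition, takes
    M = log2(kd/ctrl), and contrasts the windows in the top vs bottom
    quartile of H4K20me1 enrichment — separately for gene-overlapping and
    non-overlapping windows. Returns the mean-M gap (top minus bottom) and
    the one-sided Welch p-value (alternative: top < bottom) for both window
    classes.
    """
    genome, annotation, truth = _world(config)
    fsets = []
    for cond in ("ctrl", "set8kd"):
        for rep in range(1, config.n_replicates + 1):
            fsets.append(
                simulate_fragments(truth, annotation, genome, "atac", cond, rep, config)
            )
    me1 = simulate_fragments(truth, annotation, genome, "me1", "ctrl", 1, config)
    h4 = simulate_fragments(truth, annotation, genome, "h4", "ctrl", 1, config)
    windows = quantify.make_windows(genome)
    counts = quantify.count_matrix(windows, fsets + [me1, h4])
    counts, _ = quantify.filter_low_signal(counts, [h4.label], min_total_count)
    fpkm = quantify.fpkm_normalize(counts)
    atac_cols = [fs.label for fs in fsets]
    qn = normalize.quantile_normalize(fpkm.values[atac_cols])
    by_cond = normalize.average_replicates(qn, {fs.label: fs.condition for fs in fsets})
    ma = normalize.ma_transform(by_cond["set8kd"], by_cond["ctrl"],
                                pseudocount=DEFAULT_PSEUDOCOUNT)
    enrichment = normalize.log2_enrichment(
        fpkm.values[me1.label], fpkm.values[h4.label], pseudocount=DEFAULT_PSEUDOCOUNT
    )
    kept = quantify.make_windows(genome).subset(fpkm.values.index)
    overlap = quantify.classify_overlap(kept, quantify.genes_as_regions(annotation))
    out = {}
    for name, mask in (
        ("genic", overlap["overlapping"]),
        ("intergenic", ~overlap["overlapping"]),
    ):
        e, m = enrichment[mask], ma["M"][mask]
        q1, q3 = e.quantile(0.25), e.quantile(0.75)
        top, bottom = m[e >= q3], m[e <= q1]
        _, p = stats.ttest_ind(top, bottom, equal_var=False, alternative="less")
        out[f"{name}_gap"] = float(top.mean() - bottom.mean())
        out[f"{name}_p"] = float(p)
    return out


def planted_cluster_bubble(
    config: SimulationConfig,
    k: int = 10,
    n_restarts: int = 10,
    n_bins: int = 20,
    min_cluster_frac: float = 0.01,
) -> dict:
    """Down-regulation bubble of the planted housekeeping-enriched cluster.

    Clusters intragenic H4K20me1 profiles (ctrl + knockdown tracks), runs the
    stand-in DE test, computes the cluster x direction enrichment, and
    reports the "down" bubble of the cluster most enriched in housekeeping
    genes among clusters holding at least ``min_cluster_frac`` of genes.
    """
    genome, annotation, truth = _world(config)
    tracks = {}
    for cond in ("ctrl", "set8kd"):
        fs = simulate_fragments(truth, annotation, genome, "me1", cond, 1, config)
        tracks[fs.label] = fs
    features = cl.build_profile_features(
        annotation, tracks, genome, track_order=sorted(tracks), n_bins=n_bins
    )
    result = cl.kmeans_profiles(features, k=k, n_restarts=n_restarts, seed=config.seed)
    expression = simulate_expression(truth, config)
    de = cl.de_test_standin(expression, _expression_grouping(expression))
    bubbles = cl.cluster_de_enrichment(result, de.loc[result.labels.index])
    hk = pd.Series(
        annotation["is_housekeeping"].to_numpy(),
        index=pd.Index(annotation["symbol"], name="symbol"),
    )
    sizes = result.labels.value_counts()
    big = sizes[sizes >= min_cluster_frac * len(result.labels)].index
    hk_frac = {c: float(hk[result.labels == c].mean()) for c in big}
    target = max(hk_frac, key=hk_frac.get)
    row = bubbles[
        (bubbles["cluster"] == target) & (bubbles["direction"] == "down")
    ].iloc[0]
    return {
        "cluster": int(target),
        "cluster_size": int(row["cluster_size"]),
        "hk_fraction": hk_frac[target],
        "log2_fold": float(row["log2_fold"]),
        "padj": float(row["padj"]),
        "down_fraction": float((de["direction"] == "down").mean()),
    }


def null_config(seed: int, n_genes: int = 5000) -> SimulationConfig:
    """Default conditions with every planted effect switched off."""
    return SimulationConfig(
        seed=seed, n_genes=n_genes, n_chromosomes=4,
        rho_me1_acc=0.0, rho_acc_expr=0.0, me3_anticorr=0.0,
        hk_me1_boost=0.0, short_gene_me1_slope=0.0,
        kd_me1_residual=1.0, kd_acc_effect=0.0, kd_expr_effect=0.0,
    )


def null_de_fraction(config: SimulationConfig) -> float:
    """Fraction of raw Welch p-values below 0.05 on null expression data."""
    _, annotation, truth = _world(config)
    expression = simulate_expression(truth, config)
    de = cl.de_test_standin(expression, _expression_grouping(expression))
    return float((de["p"] < 0.05).mean())


def hk_profile_separation(config: SimulationConfig, n_body_bins: int = 100,
                          n_flank_bins: int = 50) -> dict:
    """Housekeeping vs non-housekeeping mean H4K20me1 metagene profiles.

    Returns the per-body-bin minimum of (HK mean - non-HK mean) and the mean
    log2 HK/non-HK ratio over body bins.
    """
    from .metagene import group_profiles, profile_matrix

    genome, annotation, truth = _world(config)
    me1 = simulate_fragments(truth, annotation, genome, "me1", "ctrl", 1, config)
    profiles = profile_matrix(
        me1, annotation, genome, n_body_bins=n_body_bins, n_flank_bins=n_flank_bins
    )
    labels = pd.Series(
        np.where(annotation["is_housekeeping"], "hk", "non_hk"),
        index=pd.Index(annotation["symbol"], name="symbol"),
    )
    curves = group_profiles(profiles, labels)
    body = curves[curves["bin"].str.startswith("b")]
    hk = body[body["group"] == "hk"].set_index("bin")["mean"]
    non = body[body["group"] == "non_hk"].set_index("bin")["mean"]
    return {
        "min_body_gap": float((hk - non).min()),
        "mean_log2_ratio": float(np.log2(hk / non).mean()),
    }
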