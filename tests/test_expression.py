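"""Differential expression: NB Wald test behaviour, BH adjustment, the
detection-fraction filter ladder, and the bundled worked-example tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import tiltpipe as tp
from tiltpipe.errors import InvalidConfigError, InvalidInputError
from tiltpipe.expression import (
    ALPHA,
    LFC_CUTOFF,
    THRESHOLD_LADDER,
    bh_adjust,
    build_candidate_table,
    detection_fraction,
    nb_wald_test,
    size_factors,
)
from tiltpipe.io import load_example_candidates, load_example_insitu_panel


def _sim(seed=0, **kw):
    cfg = tp.SimConfig(seed=seed, n_fish_per_genotype=1, n_neurons_per_fish=1, **kw)
    counts, cond, atlas, cluster, truth = tp.simulate_counts_and_atlas(cfg)
    return tp.CountMatrix(counts, cond), tp.AtlasDetection(atlas, cluster), truth


# --- detection fraction ----------------------------------------------------
def test_detection_fraction_small_cases():
    det = pd.DataFrame([[1, 0], [0, 0]], index=["g1", "g2"], columns=["c1", "c2"])
    cl = pd.Series(["projection", "projection"], index=["c1", "c2"])
    frac = detection_fraction(tp.AtlasDetection(det, cl))
    assert frac["g1"] == 0.5
    assert frac["g2"] == 0.0
    with pytest.raises(InvalidInputError):
        detection_fraction(tp.AtlasDetection(det, cl), cluster="absent")


# --- BH --------------------------------------------------------------------
def test_bh_small_oracles():
    assert bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)
    np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)
    with pytest.raises(InvalidInputError):
        bh_adjust(np.array([0.5, 1.5]))
    with pytest.raises(InvalidConfigError):
        bh_adjust(np.array([0.1, 0.2]), m=1)


def _brute_force_bh(p, m):
    """Step-up by hand: padj_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj = [min(ranked[i:]) for i in range(len(p))]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_matches_brute_force_and_statsmodels_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(2, 50))
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, _brute_force_bh(p, len(p)), atol=1e-12)
        np.testing.assert_allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_bh_with_wider_universe():
    p = np.array([0.001, 0.002])
    np.testing.assert_allclose(bh_adjust(p, m=10), _brute_force_bh(p, 10))


# --- NB Wald test ----------------------------------------------------------
def test_identical_counts_give_zero_lfc_and_p_of_one():
    counts = pd.DataFrame(
        np.tile([[50], [200], [10]], 6), index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(6)],
    )
    cond = pd.Series(["null"] * 3 + ["sibling"] * 3, index=counts.columns)
    res = nb_wald_test(tp.CountMatrix(counts, cond))
    np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-12)
    assert (res["p_value"] > 0.99).all()


def test_all_zero_genes_are_flagged_and_excluded():
    counts = pd.DataFrame(
        [[0, 0, 0, 0], [5, 6, 7, 8]], index=["dead", "ok"], columns=list("abcd")
    )
    cond = pd.Series(["null", "null", "sibling", "sibling"], index=list("abcd"))
    res = nb_wald_test(tp.CountMatrix(counts, cond))
    assert bool(res.loc["dead", "all_zero"])
    assert np.isnan(res.loc["dead", "p_value"])


def test_single_sample_condition_is_rejected():
    counts = pd.DataFrame([[1, 2, 3]], index=["g"], columns=list("abc"))
    cond = pd.Series(["null", "sibling", "sibling"], index=list("abc"))
    with pytest.raises(InvalidInputError):
        nb_wald_test(tp.CountMatrix(counts, cond))


def test_size_factors_scale_with_library_depth():
    rng = np.random.default_rng(1)
    base = rng.poisson(100, size=(200, 1))
    counts = pd.DataFrame(
        np.hstack([rng.poisson(base), rng.poisson(base * 2)]),
        index=[f"g{i}" for i in range(200)], columns=["a", "b"],
    )
    sf = size_factors(counts)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=0.1)


def test_null_simulation_type_one_error_is_calibrated():
    counts, _, truth = _sim(seed=2, n_genes=2000, planted_gene_fraction=0.0)
    res = nb_wald_test(counts)
    rate = (res["p_value"].dropna() < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_planted_fold_changes_are_detected_with_high_power():
    counts, atlas, truth = _sim(
        seed=3, n_genes=2000, planted_gene_fraction=0.05, planted_lfc=4.0,
        mean_count_range=(100.0, 100.0), nb_dispersion=0.05,
        nb_dispersion_lognorm_sigma=0.0,
    )
    res = nb_wald_test(counts)
    det = detection_fraction(atlas)
    table = build_candidate_table(res, det).table
    planted = [g for g, l in truth.gene_lfc.items() if l != 0.0]
    hits = table.loc[planted, "passes_significance"]
    assert hits.mean() >= 0.90


def test_planted_genes_rank_above_null_genes_by_significance():
    counts, _, truth = _sim(
        seed=4, n_genes=1000, planted_gene_fraction=0.05, planted_lfc=4.0,
        mean_count_range=(100.0, 100.0), nb_dispersion=0.05,
        nb_dispersion_lognorm_sigma=0.0,
    )
    res = nb_wald_test(counts).dropna(subset=["p_value"])
    labels = np.array([truth.gene_lfc[g] != 0.0 for g in res.index])
    # AUC from rank-sum of -log p (ties broken by rank average)
    from scipy.stats import rankdata

    ranks = rankdata(-np.log10(res["p_value"] + 1e-300))
    n1, n0 = labels.sum(), (~labels).sum()
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    assert auc >= 0.95


def test_null_double_criterion_is_no_looser_than_p_adjusted_alone():
    counts, atlas, _ = _sim(seed=5, n_genes=500, planted_gene_fraction=0.0)
    table = build_candidate_table(nb_wald_test(counts), detection_fraction(atlas)).table
    both = table["passes_significance"].mean()
    p_only = (table["p_adjusted"] < ALPHA).mean()
    assert both <= p_only


# --- filtering -------------------------------------------------------------
def test_zero_threshold_filter_is_identity():
    counts, atlas, _ = _sim(seed=6, n_genes=200)
    base = build_candidate_table(nb_wald_test(counts), detection_fraction(atlas))
    filt = tp.apply_reference_filter(base, 0.0)
    assert filt.universe_size == base.universe_size
    pd.testing.assert_index_equal(filt.table.index, base.table.index)


def test_filter_threshold_validation():
    counts, atlas, _ = _sim(seed=6, n_genes=50)
    base = build_candidate_table(nb_wald_test(counts), detection_fraction(atlas))
    with pytest.raises(InvalidConfigError):
        tp.apply_reference_filter(base, 150.0)


def test_raw_p_values_are_universe_independent():
    """Filtering then testing equals testing then subsetting for raw p;
    only the BH adjustment depends on the universe."""
    counts, atlas, _ = _sim(seed=7, n_genes=300)
    base = build_candidate_table(nb_wald_test(counts), detection_fraction(atlas))
    filt = tp.apply_reference_filter(base, 10.0, counts=None)
    sub = base.table.loc[filt.table.index]
    np.testing.assert_allclose(filt.table["p_value"], sub["p_value"])
    np.testing.assert_allclose(
        filt.table["p_adjusted"], bh_adjust(sub["p_value"].to_numpy()), atol=1e-12
    )


def test_universe_sizes_are_monotone_in_threshold():
    counts, atlas, _ = _sim(seed=8, n_genes=300, atlas_n_cells=200)
    sweep = tp.threshold_sweep(counts, atlas)
    sizes = sweep["universe_size"].to_numpy()
    assert (np.diff(sizes) <= 0).all()
    assert sweep.loc[0, "universe_size"] == 300


def test_uniform_full_detection_makes_all_universes_identical():
    g = 100
    counts, atlas, _ = _sim(
        seed=9, n_genes=g, detection_rate_distribution=np.ones(g)
    )
    sweep = tp.threshold_sweep(counts, atlas)
    assert (sweep["universe_size"] == g).all()
    assert sweep["n_deg"].nunique() == 1


def test_planted_de_among_high_detection_genes_survives_until_their_level():
    """Plant DE only in genes pinned at 40% atlas detection: the DEG count
    must be stable through the 30% rung and fall to zero at 50%."""
    counts, atlas, truth = _sim(
        seed=10, n_genes=400, planted_gene_fraction=0.05, planted_lfc=4.0,
        planted_detection_rate=0.40, mean_count_range=(100.0, 100.0),
        nb_dispersion=0.05, nb_dispersion_lognorm_sigma=0.0,
        detection_rate_distribution=np.full(400, 0.02),
    )
    sweep = tp.threshold_sweep(counts, atlas).set_index("threshold_pct")
    assert sweep.loc[30, "n_deg"] >= 0.9 * sweep.loc[0, "n_deg"] > 0
    assert sweep.loc[50, "n_deg"] == 0


def test_genes_missing_from_atlas_get_zero_detection():
    counts, atlas, _ = _sim(seed=11, n_genes=50)
    det = detection_fraction(atlas).iloc[:40]  # drop 10 genes from the atlas
    table = build_candidate_table(nb_wald_test(counts), det)
    dropped = counts.counts.index[40:]
    assert (table.table.loc[dropped, "detection_fraction"] == 0.0).all()
    assert table.table.attrs["n_missing_from_atlas"] == 10


# --- bundled worked examples -----------------------------------------------
def test_example_candidates_all_fall_below_ten_percent_detection():
    """Every reported candidate is lowly detected (max 6.6%), so the 10%
    reference filter removes the entire list."""
    cands = load_example_candidates()
    assert cands["detection_pct"].max() == pytest.approx(6.6)
    survivors = cands[cands["detection_pct"] >= 10.0]
    assert len(survivors) == 0


def test_insitu_panel_significance_criteria():
    """Of the eight genes in the validation panel, exactly six satisfy
    p_adjusted < 0.05 and |log2FC| > 2; the near-significant one and the
    highly-detected control fail."""
    panel = load_example_insitu_panel()
    passes = (panel["p_adjusted"] < ALPHA) & (panel["log2_fold_change"].abs() > LFC_CUTOFF)
    assert passes.sum() == 6
    assert not passes["mapk6"]  # adjusted p = 0.06
    assert not passes["evx2"]   # log2FC = 0.46
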