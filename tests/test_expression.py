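"""Normalisation, the time-course gate, profile clustering, pairwise DE
and concordance."""

import numpy as np
import pandas as pd
import pytest

from berrysync import expression, synthetic
from berrysync.expression import (
    MODEL_PROFILES,
    compute_cpm,
    compute_rpkm,
    concordance_sets,
    pairwise_de,
    profile_cluster,
    rpkm_filter,
    sample_overview,
    timecourse_test,
    tmm_factors,
)


def test_cpm_rpkm_definitions():
    counts = pd.DataFrame({"s1": [500, 999_500]}, index=["g1", "g2"])
    cpm = compute_cpm(counts)
    assert cpm.loc["g1", "s1"] == pytest.approx(500.0)
    assert cpm["s1"].sum() == pytest.approx(1e6)
    rpkm = compute_rpkm(counts, pd.Series({"g1": 1000, "g2": 1000}))
    assert rpkm.loc["g1", "s1"] == pytest.approx(500.0)  # 1 kb: RPKM == CPM


def test_rpkm_rejects_zero_length():
    counts = pd.DataFrame({"s1": [1, 2]}, index=["g1", "g2"])
    with pytest.raises(ValueError):
        compute_rpkm(counts, pd.Series({"g1": 0, "g2": 100}))


def test_rpkm_filter_drops_low_expression_everywhere(design):
    counts = pd.DataFrame(
        {s: [2, 999_998] for s in design["sample_id"]}, index=["low", "high"])
    lengths = pd.Series({"low": 10_000, "high": 1000})
    kept = rpkm_filter(counts, lengths, design)
    assert list(kept) == ["high"]  # low: CPM 2, 10 kb -> RPKM 0.2 everywhere


def test_tmm_identical_columns_are_unity():
    rng = np.random.default_rng(0)
    col = rng.poisson(50, 200)
    counts = pd.DataFrame({"a": col, "b": col, "c": col})
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_matches_edger_on_frozen_fixture():
    """Cross-check against edgeR::calcNormFactors on a frozen 50-gene
    fixture (factors printed by edgeR 4.0.16)."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1.0, 50)
    counts = pd.DataFrame({
        "s1": rng.poisson(mu * 1.0), "s2": rng.poisson(mu * 2.0),
        "s3": rng.poisson(mu * 0.7), "s4": rng.poisson(mu * 1.3)})
    edger = [0.981384, 1.003179, 1.002270, 1.013439]
    assert np.allclose(tmm_factors(counts), edger, atol=1e-5)


def test_tmm_recovers_planted_library_scale():
    rng = np.random.default_rng(0)
    mu = rng.lognormal(3, 1.2, 2000)
    counts = pd.DataFrame({"s1": rng.poisson(mu), "s2": rng.poisson(2.0 * mu)})
    tmm = tmm_factors(counts)
    eff = counts.sum(axis=0) * tmm
    assert eff["s2"] / eff["s1"] == pytest.approx(2.0, rel=0.05)
    assert np.exp(np.mean(np.log(tmm))) == pytest.approx(1.0)  # geometric mean 1


def test_tmm_rejects_single_sample_and_zero_library():
    with pytest.raises(ValueError):
        tmm_factors(pd.DataFrame({"a": [1, 2]}))
    with pytest.raises(ValueError):
        tmm_factors(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


def _log_expr(counts):
    return np.log2(compute_cpm(counts, tmm=tmm_factors(counts)) + 1.0)


def test_timecourse_null_type_one_controlled(design, null_counts):
    counts, lengths, _ = null_counts
    tc = timecourse_test(_log_expr(counts), design, "syrah")
    assert tc["significant"].mean() <= 2 * 0.05  # gate type-I <= 2x nominal
    assert tc["p_value"].between(0, 1).all()


def test_timecourse_power_on_planted_decline(design, switchoff_counts):
    counts, lengths, truth = switchoff_counts
    tc = timecourse_test(_log_expr(counts), design, "syrah")
    off = truth.index[truth["archetype"] == "switch_off"]
    assert tc.loc[off, "significant"].mean() >= 0.9


def test_timecourse_r2_gate_excludes_weak_fits():
    """Highly significant but weak-R^2 genes stay outside the gate."""
    rng = np.random.default_rng(8)
    info = synthetic.stage_design(genotypes=("syrah",), n_reps=30)
    t = info["stage"].map({"G": 0, "P": 1, "S": 2}).to_numpy()
    y = 0.3 * t + rng.normal(0, 1.0, (50, len(info)))  # small slope, big noise
    frame = pd.DataFrame(y, columns=info["sample_id"],
                         index=[f"g{i}" for i in range(50)])
    tc = timecourse_test(frame, info, "syrah")
    weak = tc[(tc["fdr"] < 0.05) & (tc["r_squared"] < 0.7)]
    assert len(weak) > 0
    assert not weak["significant"].any()


def test_timecourse_skips_zero_variance_genes(design, null_counts):
    counts, _, _ = null_counts
    log_expr = _log_expr(counts).iloc[:50].copy()
    log_expr.iloc[0] = 3.0  # constant gene
    with pytest.warns(UserWarning):
        tc = timecourse_test(log_expr, design, "syrah")
    assert np.isnan(tc["p_value"].iloc[0])


def test_model_profiles_enumeration():
    assert len(MODEL_PROFILES) == 24
    for vec, shape in MODEL_PROFILES.values():
        assert vec.mean() == pytest.approx(0.0)
        assert shape in "ABCD"
    # the [4, 2, 0] profile mean-centres to [2, 0, -2] and is shape B
    match = [shape for vec, shape in MODEL_PROFILES.values()
             if np.allclose(vec, [2.0, 0.0, -2.0])]
    assert match == ["B"]


def test_profile_cluster_shapes(design):
    stages = design["stage"].map({"G": 0, "P": 1, "S": 2}).to_numpy()
    rows = {
        "down": 8.0 - 2.0 * stages,            # monotone decreasing -> B
        "up": 2.0 + 2.0 * stages,              # monotone increasing -> A
        "peak": 4.0 + 3.0 * (stages == 1),     # up-peak at P -> C
        "dip": 4.0 - 3.0 * (stages == 1),      # down-peak at P -> D
        "flatg": np.full(len(design), 5.0),    # zero variance -> unassigned
    }
    frame = pd.DataFrame(rows, index=design["sample_id"]).T
    prof = profile_cluster(frame, design)
    assert prof.loc["down", "merged_cluster"] == "B"
    assert prof.loc["up", "merged_cluster"] == "A"
    assert prof.loc["peak", "merged_cluster"] == "C"
    assert prof.loc["dip", "merged_cluster"] == "D"
    assert prof.loc["flatg", "merged_cluster"] == "none"


def test_switch_off_genes_land_in_cluster_b(design, switchoff_counts):
    counts, lengths, truth = switchoff_counts
    log_expr = _log_expr(counts)
    tc = timecourse_test(log_expr, design, "syrah")
    prof = profile_cluster(log_expr, design, genes=tc.index[tc["significant"]])
    off = truth.index[truth["archetype"] == "switch_off"]
    in_b = (tc.loc[off, "significant"]
            & (prof.reindex(off)["merged_cluster"] == "B"))
    assert in_b.mean() >= 0.85


def test_pairwise_de_null_and_power(design, null_counts, switchoff_counts):
    counts, _, _ = null_counts
    de_null = pairwise_de(counts, design, "syrah")
    assert 0.01 <= (de_null["p_value"] < 0.05).mean() <= 0.10  # ~ nominal
    assert de_null["significant"].mean() <= 0.005

    counts_s, _, truth_s = switchoff_counts
    de = pairwise_de(counts_s, design, "syrah")
    off = truth_s.index[truth_s["archetype"] == "switch_off"]
    assert de.loc[off, "significant"].mean() >= 0.8
    assert (de.loc[off, "direction"] == "down").mean() >= 0.95


def test_pairwise_de_lfc_tracks_truth(design, switchoff_counts):
    counts, _, truth = switchoff_counts
    de = pairwise_de(counts, design, "syrah")
    off = truth.index[truth["archetype"] == "switch_off"]
    err = de.loc[off, "log2_fold_change"] - np.log2(0.2)
    assert abs(err.mean()) <= 0.2  # within 0.2 of the true 5-fold repression


def test_pairwise_de_drops_all_zero_genes(design, null_counts):
    counts, _, _ = null_counts
    counts = counts.copy()
    counts.iloc[0] = 0
    de = pairwise_de(counts, design, "syrah")
    assert counts.index[0] not in de.index


def test_pairwise_de_needs_replicates(design, null_counts):
    counts, _, _ = null_counts
    solo = design[design["replicate"] == 1]
    with pytest.raises(ValueError):
        pairwise_de(counts[solo["sample_id"]], solo, "syrah")


def test_concordance_enumeration():
    def frame(sig):
        return pd.DataFrame(
            {"significant": [True] * len(sig), "direction": list(sig.values())},
            index=list(sig))

    de = {
        "g1": frame({"a": "up", "b": "down"}),
        "g2": frame({"a": "up", "b": "down"}),
        "g3": frame({"a": "up", "b": "up"}),
    }
    out = concordance_sets(de)
    assert out["common_up"] == ["a"]
    assert out["discordant"] == ["b"]
    assert out["common_down"] == []

    empty = {k: frame({}) for k in "xyz"}
    out2 = concordance_sets(empty)
    assert not (out2["common_up"] or out2["common_down"] or out2["discordant"])


def test_sample_overview_duplicates_and_separation(design, switchoff_counts):
    counts, _, _ = switchoff_counts
    log_expr = _log_expr(counts)
    dup = log_expr.copy()
    dup.iloc[:, 1] = dup.iloc[:, 0]  # duplicated sample -> distance 0
    ov = sample_overview(dup)
    first_merge = ov.linkage[0]
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)
    assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    ov2 = sample_overview(log_expr)
    ratios = ov2.explained_variance_ratio
    assert ratios.sum() <= 1.0 + 1e-9
    # the G vs S switch-off contrast dominates PC1
    info = design.set_index("sample_id")
    pc1 = ov2.pca_coordinates["PC1"]
    g_mean = pc1[info["stage"] == "G"].mean()
    s_mean = pc1[info["stage"] == "S"].mean()
    assert abs(g_mean - s_mean) > pc1.std()
    assert ratios[0] > 0.5
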