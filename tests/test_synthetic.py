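"""Synthetic cohort generator: growth, solutes, counts, promoters and the
calendar-pooling artefact."""

import numpy as np
import pandas as pd
import pytest

from berrysync import synthetic
from berrysync.staging import normalize_growth


def _noiseless_config(**kw):
    defaults = dict(n_berries=4, asynchrony_window=0.0, noise_sd=0.0,
                    softening_volume_cv=0.0, growth_gain_sd=0.0,
                    ripen_duration=(25.0, 25.0), shrivel_rate_sigma=0.0, seed=0)
    defaults.update(kw)
    return synthetic.CohortConfig(**defaults)


def test_config_invariants_enforced():
    with pytest.raises(synthetic.ConfigError):
        synthetic.CohortConfig(n_berries=0)
    with pytest.raises(synthetic.ConfigError):
        synthetic.CohortConfig(growth_gain=1.0)
    with pytest.raises(synthetic.ConfigError):
        synthetic.CohortConfig(asynchrony_window=-1.0)


def test_growth_peak_equals_gain_without_noise():
    cfg = _noiseless_config(growth_gain=2.0)
    for traj in synthetic.simulate_growth(cfg):
        model = traj.meta["model"]
        # the berry's peak is exactly gain x softening volume ...
        assert model.relative_volume(model.peak_day) == pytest.approx(2.0, abs=1e-12)
        # ... and no observation exceeds it (pictures may miss the exact day)
        v = normalize_growth(traj)
        assert v.max() <= 2.0 + 1e-9
        assert v.max() == pytest.approx(2.0, abs=0.02)
        assert np.all(traj.volume > 0)


def test_growth_same_seed_is_bit_identical():
    cfg = synthetic.CohortConfig(n_berries=10, seed=42)
    a = synthetic.simulate_growth(cfg)
    b = synthetic.simulate_growth(cfg)
    for ta, tb in zip(a, b):
        assert ta.berry_id == tb.berry_id
        assert np.array_equal(ta.volume, tb.volume)
        assert ta.softening_day == tb.softening_day


def test_softening_dates_unique_and_span_asynchrony_window():
    cfg = synthetic.CohortConfig(n_berries=200, asynchrony_window=21.0, seed=3)
    soft = np.array([t.softening_day for t in synthetic.simulate_growth(cfg)])
    assert len(np.unique(soft)) == 200
    # order statistics of U(0, 21) at n=200: the range covers nearly 21 d
    assert 0.85 * 21 <= soft.max() - soft.min() <= 21.0


def test_solutes_flat_after_peak_and_plateau_concentration():
    cfg = _noiseless_config()
    params = synthetic.GENOTYPES["mv032"]  # 0.8 M plateau
    traj = synthetic.simulate_growth(cfg)[0]
    model = traj.meta["model"]
    days = np.array([model.peak_day, model.peak_day + 14.0])
    series = synthetic.simulate_solutes(traj, params, conc_noise_sd=0.0, days=days)
    # amount at peak equals amount 14 d later (phloem stopped)
    assert series["true_sugar_mmol"].iloc[0] == pytest.approx(
        series["true_sugar_mmol"].iloc[1], rel=1e-12)
    # glucose + fructose concentration at arrest ~= the genotype plateau
    conc = series[["glucose_mol_l", "fructose_mol_l"]].iloc[0].sum()
    assert conc == pytest.approx(params.sugar_plateau, rel=0.01)


def test_potassium_flux_ratio_and_conservation():
    cfg = _noiseless_config()
    params = synthetic.GENOTYPES["syrah"]  # sugar:K+ molar flux 30
    traj = synthetic.simulate_growth(cfg)[0]
    model = traj.meta["model"]
    days = np.array([model.softening_day, model.peak_day])
    s = synthetic.simulate_solutes(traj, params, conc_noise_sd=0.0, days=days)
    d_sugar = s["true_sugar_mmol"].iloc[1] - s["true_sugar_mmol"].iloc[0]
    d_k = s["true_potassium_meq"].iloc[1] - s["true_potassium_meq"].iloc[0]
    assert d_sugar / d_k == pytest.approx(params.k_flux_ratio, rel=1e-9)
    # tartrate never increases; amounts never negative
    full = synthetic.simulate_solutes(traj, params, conc_noise_sd=0.0)
    assert (np.diff(full["true_tartrate_meq"]) <= 1e-12).all()
    assert (full["true_malate_meq"] >= 0).all()
    assert np.diff(full["true_malate_meq"]).max() <= 1e-12
    assert full["true_tartrate_meq"].iloc[-1] / full["true_tartrate_meq"].iloc[0] >= \
        params.tartrate_retention - 1e-9


def test_solutes_require_synthetic_trajectory():
    from berrysync.staging import BerryTrajectory, StagingError

    bare = BerryTrajectory("x", np.array([0.0, 1.0, 2.0]), np.ones(3), 0.0)
    with pytest.raises(StagingError):
        synthetic.simulate_solutes(bare, synthetic.GENOTYPES["syrah"])


def test_counts_cpm_definition_and_fold_convergence(design):
    info = design.set_index("sample_id")
    g_cols = info.index[info["stage"] == "G"]
    s_cols = info.index[info["stage"] == "S"]

    # mean count at G tracks the planted 500 CPM in a 1e6 library
    arch = {"switch_off": (synthetic.ExpressionArchetype("switch_off", 0.2, 500.0), 1.0)}
    counts, _, truth = synthetic.simulate_counts(
        design, archetypes=arch, n_genes=300, library_size=1e6, seed=0,
        genotype_sd=0.0, library_cv=0.0)
    assert counts[g_cols].mean(axis=1).mean() == pytest.approx(500.0, rel=0.05)
    assert (counts.dtypes == np.int64).all()
    assert set(truth["archetype"]) == {"switch_off"}

    # against a flat background, the realised CPM fold converges to 0.2
    arch2 = {
        "flat": (synthetic.ExpressionArchetype("flat", 1.0), 0.9),
        "switch_off": (synthetic.ExpressionArchetype("switch_off", 0.2, 500.0), 0.1),
    }
    counts2, _, truth2 = synthetic.simulate_counts(
        design, archetypes=arch2, n_genes=2000, library_size=1e6, seed=1,
        genotype_sd=0.0, library_cv=0.0)
    cpm = counts2 / counts2.sum(axis=0) * 1e6
    off = truth2.index[truth2["archetype"] == "switch_off"]
    ratio = cpm.loc[off, s_cols].mean(axis=1).sum() / cpm.loc[off, g_cols].mean(axis=1).sum()
    assert ratio == pytest.approx(0.2, rel=0.05)  # 80% repression recovered


def test_counts_zero_library_errors(design):
    with pytest.raises(synthetic.ConfigError):
        synthetic.simulate_counts(design, n_genes=10, library_size=0.0)


def test_promoters_planted_sites_recovered_and_tss_rule():
    from berrysync import promoters as pr

    lib = {"m1": "TGACGT"}
    genes = tuple(f"gene{i:03d}" for i in range(60))
    groups = [synthetic.PromoterGroupSpec("grp", genes, ("m1",), center=50, jitter=20)]
    sim = synthetic.simulate_promoters(groups, lib, seed=5)
    tss = pr.select_tss(sim.annotation_a, sim.annotation_b)
    # annotation B lost the 5'UTR, so the upstream candidate (A) always wins
    assert (tss["tss_source"] == "a").all()
    proms = pr.extract_promoters(sim.genome, tss, 1500)
    mlib = pr.load_motif_library(pd.DataFrame(
        {"motif_id": ["m1"], "consensus": ["TGACGT"]}))
    truth = sim.truth.set_index("gene_id")
    recovered = sum(
        any(h.offset == truth.loc[p.gene_id, "offset"] for h in pr.scan_motifs(p, mlib))
        for p in proms)
    assert recovered / len(proms) >= 0.95
    offsets = sim.truth["offset"]
    assert offsets.between(30, 70).all()
    assert set(sim.truth["strand"]) == {"+", "-"}  # both strands represented


def test_promoters_background_hit_rate_matches_closed_form():
    from berrysync import promoters as pr

    lib = {"m1": "TGACGT"}
    genes = tuple(f"g{i:03d}" for i in range(200))
    sim = synthetic.simulate_promoters(
        [synthetic.PromoterGroupSpec("bg", genes, ())], lib, seed=6)
    tss = pr.select_tss(sim.annotation_a, sim.annotation_b)
    proms = pr.extract_promoters(sim.genome, tss, 1500)
    mlib = pr.load_motif_library(pd.DataFrame(
        {"motif_id": ["m1"], "consensus": ["TGACGT"]}))
    total = sum(len(pr.scan_motifs(p, mlib)) for p in proms)
    expected = 200 * (1500 - 6 + 1) * 2 * 0.25**6
    assert abs(total - expected) <= 3 * np.sqrt(expected)


def test_promoters_reject_motif_longer_than_promoter():
    with pytest.raises(ValueError):
        synthetic.simulate_promoters(
            [synthetic.PromoterGroupSpec("g", ("a",), ("m1",))],
            {"m1": "A" * 2000}, promoter_length=1500)


def test_artifact_single_berry_impossible():
    cfg = _noiseless_config(n_berries=1)
    trajs = synthetic.simulate_growth(cfg)
    rep = synthetic.pooled_sampling_artifact(trajs, synthetic.GENOTYPES["syrah"],
                                             conc_noise_sd=0.0)
    assert rep.sugar_rising_days_after_peak == 0.0
    assert not rep.artefact_detected


def test_artifact_zero_asynchrony_series_identical():
    cfg = _noiseless_config(n_berries=5, asynchrony_window=0.0)
    trajs = synthetic.simulate_growth(cfg)
    rep = synthetic.pooled_sampling_artifact(trajs, synthetic.GENOTYPES["syrah"],
                                             conc_noise_sd=0.0)
    # homogeneous berries: the pooled series equals every berry's own series
    model = trajs[0].meta["model"]
    assert rep.pooled_volume_peak_day == pytest.approx(model.peak_day, abs=1.0)
    assert rep.sugar_rising_days_after_peak == 0.0
    assert np.allclose(rep.sync_sugar, rep.sync_sugar[0], rtol=1e-9)


def test_artifact_detected_on_asynchronous_cohort():
    cfg = synthetic.CohortConfig(n_berries=200, asynchrony_window=21.0, seed=0)
    trajs = synthetic.simulate_growth(cfg)
    rep = synthetic.pooled_sampling_artifact(trajs, synthetic.GENOTYPES["syrah"], seed=0)
    assert rep.artefact_detected
    assert rep.sugar_rising_days_after_peak >= 7.0
    assert rep.pooled_post_peak_sugar_slope > 0


def test_cohort_writers_roundtrip(tmp_path, default_cohort):
    from berrysync.staging import read_growth_tsv, trajectories_from_table

    path = tmp_path / "growth.tsv"
    synthetic.write_growth_tsv(default_cohort.trajectories, path)
    table = read_growth_tsv(path)
    trajs = trajectories_from_table(table)
    orig = {t.berry_id: t for t in default_cohort.trajectories}
    assert set(t.berry_id for t in trajs) == set(orig)
    for t in trajs:
        # areas were emitted from sphere-equivalent volumes; conversion
        # back must reproduce the volumes to rounding precision
        assert np.allclose(t.volume, orig[t.berry_id].volume, rtol=1e-4)
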