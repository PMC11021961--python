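"""Synthetic-data generators: design counts, determinism, planted effects."""

import json

import numpy as np
import pandas as pd
import pytest

from glycopanel.annotation import annotate_cohort, normalize_total_area, qc_select_glycans
from glycopanel.compositions import sodiated_mz
from glycopanel.simulate import (
    DIFFERENTIAL_FEATURES,
    SimulationConfig,
    default_differential_effects,
    expected_fraction_fold_changes,
    generate_cohort,
    plant_effects,
    render_spectrum,
    simulate_feature_table,
    simulate_panel_cohort,
)

SMALL = dict(group_sizes={"H1": 3, "0-CAD": 3, "1-CAD": 3, "2-CAD": 3, "3-CAD": 3}, n_decoys=10)


def test_default_design_counts(default_cohort):
    assert len(default_cohort.manifest) == 159
    assert default_cohort.manifest.group_counts() == {
        "H1": 27, "0-CAD": 33, "1-CAD": 33, "2-CAD": 33, "3-CAD": 33,
    }
    assert sum(len(v) for v in default_cohort.spectra.values()) == 477


def test_render_spectrum_counting_bound_and_decoy_exclusion():
    cfg = SimulationConfig(**{**SMALL, "missing_rate": 0.3, "seed": 4})
    names = cfg.composition_names()
    rng = np.random.default_rng(0)
    true = {c: 1000.0 for c in names}
    pl = render_spectrum(true, cfg, rng)
    assert len(pl) <= len(names) + cfg.n_decoys
    theo = np.array([sodiated_mz(c) for c in names])
    # peaks far from every target are decoys and must respect the exclusion zone
    dist = np.min(np.abs(pl.mz[:, None] - theo[None, :]), axis=1)
    decoys = dist > 10 * cfg.mz_jitter_sd
    assert (dist[decoys] > cfg.decoy_exclusion).all()


def test_true_peaks_stay_within_matching_tolerance():
    cfg = SimulationConfig(**{**SMALL, "n_decoys": 0, "seed": 5})
    names = cfg.composition_names()
    rng = np.random.default_rng(1)
    hits = total = 0
    theo = np.array([sodiated_mz(c) for c in names])
    for _ in range(50):
        pl = render_spectrum({c: 1000.0 for c in names}, cfg, rng)
        dist = np.min(np.abs(pl.mz[:, None] - theo[None, :]), axis=1)
        hits += (dist <= 0.2).sum()
        total += len(pl)
    assert hits / total >= 0.99  # jitter SD 0.03 Da => ~6.7 sigma at 0.2 Da


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(**SMALL, seed=11)
    generate_cohort(cfg, out_dir=tmp_path / "a")
    generate_cohort(cfg, out_dir=tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_noiseless_cohort_recovers_true_fractions_exactly():
    cfg = SimulationConfig(
        **{**SMALL, "n_decoys": 0, "replicate_cv": 0.0, "mz_jitter_sd": 0.0, "seed": 12}
    )
    cohort = generate_cohort(cfg)
    quant = annotate_cohort(cohort.spectra, cfg.composition_names())
    fractions = normalize_total_area(quant.mean_area)
    for sid, true_areas in cohort.truth["true_areas"].items():
        true = pd.Series(true_areas)
        expected = true / true.sum()
        assert np.abs(fractions.loc[sid] - expected).max() < 1e-12


def test_ground_truth_round_trips_through_json(tmp_path):
    cfg = SimulationConfig(**{**SMALL, "effects": {"H5N4S2": {"3-CAD": 1.5}}, "seed": 13})
    generate_cohort(cfg, out_dir=tmp_path)
    truth = json.loads((tmp_path / "ground_truth.json").read_text())
    assert truth["effects"] == {"H5N4S2": {"3-CAD": 1.5}}
    assert len(truth["true_areas"]) == 15
    assert "3-CAD" in truth["expected_fraction_fold_changes"]


class TestPlantedEffects:
    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="unknown composition"):
            plant_effects(["H5N4"], {"H9N9": {"3-CAD": 2.0}})
        with pytest.raises(ValueError, match="unknown group"):
            plant_effects(["H5N4"], {"H5N4": {"9-CAD": 2.0}})

    def test_closure_direction_of_expected_fold_changes(self):
        cfg = SimulationConfig(effects={"H5N4S2": {"3-CAD": 1.5}})
        fc = expected_fraction_fold_changes(cfg, "3-CAD")
        assert fc["H5N4S2"] > 1.0
        others = fc.drop("H5N4S2")
        assert (others < 1.0).all()  # closure pushes the rest down
        assert np.allclose(others, others.iloc[0])  # uniformly, by the total factor

    def test_planted_monotone_trend_reproduced_by_pipeline(self):
        """An abundance trend over stenosis grades survives the full pipeline
        (monotone-association check of fraction vs ordinal grade)."""
        from scipy import stats

        effects = {"H5N4S2": {"0-CAD": 1.1, "1-CAD": 1.25, "2-CAD": 1.45, "3-CAD": 1.7}}
        grade = {"H1": 0, "0-CAD": 1, "1-CAD": 2, "2-CAD": 3, "3-CAD": 4}
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(
                group_sizes={g: 8 for g in grade},
                n_decoys=10, effects=effects, seed=100 + seed,
            )
            cohort = generate_cohort(cfg)
            quant = annotate_cohort(cohort.spectra, cfg.composition_names())
            fractions = normalize_total_area(quant.mean_area)
            groups = cohort.manifest.group_of().map(grade)
            tau, p = stats.kendalltau(groups.loc[fractions.index], fractions["H5N4S2"])
            hits += bool(tau > 0 and p < 0.05)
        assert hits >= 4


class TestFeatureLevelSimulators:
    def test_null_cohort_is_exchangeable(self):
        table = simulate_feature_table(seed=14)
        assert table.attrs["planted_features"] == []
        assert table.shape == (125, 75)  # 74 features + group

    def test_default_effect_map_covers_18_features(self):
        effects = default_differential_effects()
        assert set(effects) == set(DIFFERENTIAL_FEATURES)
        mults = [m for shifts in effects.values() for m in shifts.values()]
        assert all(m >= 1.5 or m <= 1 / 1.5 for m in mults)

    def test_planted_shift_moves_only_named_feature_groups(self):
        table = simulate_feature_table(
            n_per_group=2000, effects={"IGP5": {"3-CAD": 1.5}}, seed=15, n_features=6,
        )
        by_group = table.groupby("group")["IGP5"].mean()
        assert by_group["3-CAD"] / by_group["H1"] == pytest.approx(1.5, rel=0.02)
        other = table.groupby("group")["IGP4"].mean()
        assert other["3-CAD"] / other["H1"] == pytest.approx(1.0, rel=0.02)

    def test_panel_cohort_construction_auc_is_attained_by_oracle_score(self):
        """The planted discriminant reaches the configured AUC at large n."""
        from glycopanel.panels import roc_auc_delong

        big = {g: n * 20 for g, n in
               {"H1": 27, "0-CAD": 33, "1-CAD": 33, "2-CAD": 33, "3-CAD": 33}.items()}
        table = simulate_panel_cohort(group_sizes=big, construction_auc=0.9, seed=16)
        info = table.attrs["informative_features"]
        score = table[info].sum(axis=1)
        y = table["group"].isin(["1-CAD", "2-CAD", "3-CAD"]).astype(float)
        auc, _, _ = roc_auc_delong(score, y)
        assert auc == pytest.approx(0.9, abs=0.01)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature_table(effects={"IGP999": {"3-CAD": 2.0}})
        with pytest.raises(ValueError):
            simulate_panel_cohort(construction_auc=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(group_sizes={"H1": 1})
        with pytest.raises(ValueError):
            SimulationConfig(effects={"H5N4": {"3-CAD": -1.0}})
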