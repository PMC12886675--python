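"""Synthetic-cohort contracts: severity labels, chronic sampling structure,
acute intervention dynamics and panel-table invariants."""

import numpy as np
import pandas as pd
import pytest

from empatch import cohort
from empatch.cohort import (
    CohortConfig,
    InterventionProtocol,
    severity,
    simulate_acute,
    simulate_chronic,
    validate_panels,
    zero_effect_config,
)


class TestSeverity:
    def test_reference_group_is_zero(self):
        cfg = CohortConfig(n_per_group=2)
        for week in range(cfg.weeks + 1):
            assert severity("CON", week, cfg) == 0.0

    def test_prediet_baseline_is_zero(self):
        cfg = CohortConfig(n_per_group=2)
        assert severity("HFFD", 0, cfg) == 0.0

    def test_linear_ramp_reaches_ceiling(self):
        cfg = CohortConfig(n_per_group=2)
        assert severity("HFFSD", 4, cfg) == pytest.approx(1.0)
        assert severity("HFFSD", 2, cfg) == pytest.approx(0.5)

    def test_saltier_diet_dominates(self):
        cfg = CohortConfig(n_per_group=2)
        for week in range(cfg.weeks + 1):
            assert severity("HFFSD", week, cfg) >= severity("HFFD", week, cfg)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            severity("KETO", 1, CohortConfig(n_per_group=2))

    def test_week_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            severity("HFFD", 9, CohortConfig(n_per_group=2))


class TestChronic:
    def test_panel_count(self):
        df = simulate_chronic(CohortConfig(n_per_group=10, seed=1))
        assert len(df) == 10 * 3 * 5

    def test_seed_determinism_bit_identical(self):
        cfg = CohortConfig(n_per_group=6, seed=9)
        a = simulate_chronic(cfg)
        b = simulate_chronic(CohortConfig(n_per_group=6, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_control_mean_matches_baseline(self):
        cfg = CohortConfig(n_per_group=60, seed=3)
        df = simulate_chronic(cfg)
        sub = df[(df.group == "CON") & (df.week == 4)]
        # total per-sample SD includes the animal intercept component
        sd_tot = cfg.baseline_sds["glucose_mM"] * np.sqrt(1 + cfg.animal_sd_frac**2)
        se = sd_tot / np.sqrt(len(sub))
        assert abs(sub["glucose_mM"].mean() - cfg.baseline_means["glucose_mM"]) < 3 * se

    def test_latent_glucose_cholesterol_correlation(self):
        cfg = zero_effect_config(n_per_group=500, weeks=1, animal_sd_frac=0.0,
                                 glucose_cholesterol_rho=0.8, seed=21)
        df = simulate_chronic(cfg)
        r = np.corrcoef(df["glucose_mM"], df["cholesterol_mM"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_all_panels_satisfy_invariants(self, small_cohort):
        _, panels = small_cohort
        validate_panels(panels)

    def test_degree_zero_in_expectation_for_controls(self, small_cohort):
        _, panels = small_cohort
        con = panels[panels.group == "CON"]["degree"]
        # clipping at 0 leaves a small positive half-normal residue
        assert con.mean() < 2 * 0.02

    def test_mean_degree_strictly_increases_with_week(self, small_cohort):
        _, panels = small_cohort
        for g in ("HFFD", "HFFSD"):
            means = panels[panels.group == g].groupby("week")["degree"].mean()
            assert np.all(np.diff(means.to_numpy()) > 0)

    def test_out_of_range_effect_shift_names_channel(self):
        cfg = CohortConfig(n_per_group=2)
        cfg.effect_matrix["HFFD"]["glucose_mM"] = np.array([0, 5, 10, 20, 30.0])
        with pytest.raises(ValueError, match="glucose_mM"):
            simulate_chronic(cfg)

    def test_clipping_is_counted(self):
        cfg = CohortConfig(n_per_group=40, seed=2)
        cfg.effect_matrix["HFFSD"]["glucose_mM"] = np.array([0, 5, 10, 14, 14.4])
        df = simulate_chronic(cfg)
        assert df.attrs["clip_count"] > 0
        validate_panels(df)  # clipped values still inside the operable span

    def test_zero_effect_groups_are_exchangeable(self):
        """Label-permutation p-values on a channel mean stay roughly uniform."""
        pvals = []
        rng = np.random.default_rng(0)
        for rep in range(30):
            cfg = zero_effect_config(n_per_group=6, weeks=1, seed=1000 + rep)
            df = simulate_chronic(cfg)
            x = df["glucose_mM"].to_numpy()
            labels = df["group"].to_numpy()
            obs = np.ptp([x[labels == g].mean() for g in cohort.CHRONIC_GROUPS])
            null = []
            for _ in range(60):
                perm = rng.permutation(labels)
                null.append(np.ptp([x[perm == g].mean()
                                    for g in cohort.CHRONIC_GROUPS]))
            pvals.append(np.mean(np.asarray(null) >= obs))
        pvals = np.asarray(pvals)
        assert 0.25 < pvals.mean() < 0.75
        assert np.mean(pvals < 0.05) < 0.25


class TestAcute:
    def test_hg_pulse_peaks_at_twenty_minutes(self):
        p = InterventionProtocol(kind="HG", noise_frac=0.0)
        df = simulate_acute(p, seed=4)
        t = df["time_min"].to_numpy()
        assert t[np.argmax(df["glucose_mM"].to_numpy())] == pytest.approx(
            20.0, abs=p.dt_s / 60.0
        )

    def test_hg_mean_trajectory_peak_with_noise(self):
        p = InterventionProtocol(kind="HG")
        stack = np.stack([
            simulate_acute(p, seed=s)["glucose_mM"].to_numpy() for s in range(8)
        ])
        t = simulate_acute(p, seed=0)["time_min"].to_numpy()
        assert t[np.argmax(stack.mean(axis=0))] == pytest.approx(20.0, abs=1.0)

    def test_hg_returns_to_baseline(self):
        p = InterventionProtocol(kind="HG", noise_frac=0.0)
        df = simulate_acute(p, seed=4)
        tail = df[df.time_min >= p.peak_time_min + p.return_time_min]["glucose_mM"]
        assert np.all(tail - p.baseline_level < 0.05 * (p.peak_level - p.baseline_level))

    def test_hua_levels_match_device_observations(self):
        df = simulate_acute(InterventionProtocol(kind="HUA"), seed=6)
        pre = df[df.time_min < 10]["ua_uM"].mean()
        plateau = df[df.time_min >= 30]["ua_uM"].mean()
        assert pre == pytest.approx(160.2, rel=0.02)
        assert plateau == pytest.approx(1015.0, rel=0.02)

    def test_norm_channels_stationary(self):
        p = InterventionProtocol(kind="NORM")
        df = simulate_acute(p, seed=7)
        first, last = df[df.time_min < 10], df[df.time_min > 50]
        for c in cohort.ANALYTE_COLUMNS:
            noise_sd = p.noise_frac * cohort.DEFAULT_BASELINE_MEANS[c]
            assert abs(last[c].mean() - first[c].mean()) < 3 * noise_sd

    def test_nontarget_channels_stationary_in_hg(self):
        p = InterventionProtocol(kind="HG")
        df = simulate_acute(p, seed=8)
        for c in ("ua_uM", "cholesterol_mM", "na_mM", "k_mM", "ph"):
            noise_sd = p.noise_frac * cohort.DEFAULT_BASELINE_MEANS[c]
            drift = abs(df[df.time_min > 50][c].mean() - df[df.time_min < 10][c].mean())
            assert drift < 3 * noise_sd

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            InterventionProtocol(kind="HG", dt_s=0.0)
        with pytest.raises(ValueError):
            InterventionProtocol(kind="HG", duration_min=20.0)
        with pytest.raises(ValueError):
            InterventionProtocol(kind="HG", onset_min=25.0, peak_time_min=20.0)


def test_panel_csv_round_trip(tmp_path, small_cohort):
    cfg, panels = small_cohort
    path = tmp_path / "panels.csv"
    cohort.write_panels(panels, path, config=cfg)
    back = cohort.read_panels(path)
    assert len(back) == len(panels)
    np.testing.assert_allclose(back["glucose_mM"], panels["glucose_mM"])
    assert (tmp_path / "panels.manifest.json").exists()
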