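"""Generator determinism, noise mechanisms, and recoverability of parameters."""

import numpy as np
import pandas as pd
import pytest

from anthroagree import CohortConfig, generate_differences, generate_truth, simulate_cohort
from anthroagree.growth_reference import DAYS_PER_MONTH, Indicator
from anthroagree.quality_metrics import digit_preference_score, terminal_digit_counts
from anthroagree.synthetic_cohort import (
    apply_manual_process,
    apply_scan_process,
    corrupt_identifiers,
    load_cohort,
    write_cohort,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_children": 0},
            {"sex_ratio": 1.2},
            {"outlier_prob": -0.1},
            {"outlier_model": "gremlins"},
            {"sessions_probs": (0.5, 0.4)},
            {"missingness_prob": (0.1,)},  # shorter than n_teams
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = CohortConfig(n_children=25, seed=3)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert CohortConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            CohortConfig.from_dict({"n_chidlren": 10})


class TestTruth:
    def test_degenerate_truth_sits_at_reference_median(self, ref):
        cfg = CohortConfig.noise_free(
            n_children=5, z_mean={"whz": 0.0, "haz": 0.0}, z_sd={"whz": 0.0, "haz": 0.0}
        )
        truth = generate_truth(cfg, ref)
        for row in truth.itertuples():
            m = ref.invert(Indicator.STATURE_FOR_AGE, row.sex, row.age_months * DAYS_PER_MONTH, 0.0)
            assert row.true_stature_cm == pytest.approx(m)

    def test_sampled_z_round_trips_through_reference(self, ref):
        """The generated stature/weight reproduce the sampled z within 1e-9."""
        truth = generate_truth(CohortConfig(n_children=40, seed=11), ref)
        for row in truth.itertuples():
            z_haz = ref.zscore(
                Indicator.STATURE_FOR_AGE, row.sex, row.age_months * DAYS_PER_MONTH, row.true_stature_cm
            )
            assert z_haz == pytest.approx(row.z_haz, abs=1e-9)
            z_whz = ref.zscore(
                Indicator.WEIGHT_FOR_STATURE, row.sex, row.true_stature_cm, row.true_weight_kg
            )
            assert z_whz == pytest.approx(row.z_whz, abs=1e-9)

    def test_truth_strictly_positive(self, ref):
        truth = generate_truth(CohortConfig(n_children=80, seed=5), ref)
        assert (truth[["true_stature_cm", "true_muac_cm", "true_weight_kg"]] > 0).all().all()

    def test_coverage_gap_is_an_error(self, ref):
        cfg = CohortConfig(n_children=5, age_range_months=(6.0, 80.0))
        with pytest.raises(ValueError, match="cover"):
            generate_truth(cfg, ref)

    def test_teams_assigned_round_robin(self, ref):
        truth = generate_truth(CohortConfig(n_children=12, n_teams=3, seed=1), ref)
        assert list(truth["team"][:6]) == [1, 2, 3, 1, 2, 3]


class TestDeterminism:
    def test_identical_config_and_seed_identical_tables(self, ref):
        cfg = CohortConfig(n_children=60, seed=42)
        a = simulate_cohort(cfg, ref)
        b = simulate_cohort(cfg, ref)
        for name in ("roster", "manual", "scan"):
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_distinct_seeds_distinct_output(self, ref):
        a = simulate_cohort(CohortConfig(n_children=30, seed=1), ref)
        b = simulate_cohort(CohortConfig(n_children=30, seed=2), ref)
        assert not a["manual"]["stature_cm"].equals(b["manual"]["stature_cm"])

    def test_adding_children_preserves_existing_records(self, ref):
        """Per-child substreams: child i's record is independent of cohort size."""
        small = generate_truth(CohortConfig(n_children=10, seed=9), ref)
        large = generate_truth(CohortConfig(n_children=20, seed=9), ref)
        pd.testing.assert_frame_equal(small, large.iloc[:10].reset_index(drop=True))

    def test_csv_round_trip(self, tmp_path, ref):
        tables = simulate_cohort(CohortConfig(n_children=15, seed=4), ref)
        write_cohort(tables, tmp_path)
        again = load_cohort(tmp_path)
        assert set(again) == {"roster", "manual", "scan"}
        assert len(again["manual"]) == 15


class TestManualProcess:
    def test_noise_off_reproduces_truth(self, ref):
        cfg = CohortConfig.noise_free(n_children=20, seed=2)
        truth = generate_truth(cfg, ref)
        manual = apply_manual_process(truth, cfg)
        np.testing.assert_allclose(manual["stature_cm"], truth["true_stature_cm"])
        np.testing.assert_allclose(manual["muac_cm"], truth["true_muac_cm"])
        np.testing.assert_allclose(manual["weight_kg"], truth["true_weight_kg"])

    def test_full_digit_preference_concentrates_terminal_digits(self, ref):
        """Always rounding to the 0.5-cm grid drives DPS to ~66.7 (two digits)."""
        cfg = CohortConfig.noise_free(
            n_children=800,
            seed=6,
            digit_pref_prob={"stature": 1.0, "muac": 1.0},
            manual_noise_sd_cm={"stature": 0.3, "muac": 0.3},
        )
        truth = generate_truth(cfg, ref)
        manual = apply_manual_process(truth, cfg)
        counts = terminal_digit_counts(manual["stature_cm"], resolution=0.1)
        assert counts[0] + counts[5] == 800
        assert digit_preference_score(counts).dps == pytest.approx(66.7, abs=1.0)

    def test_empty_truth_rejected(self, ref):
        cfg = CohortConfig.noise_free(n_children=5)
        with pytest.raises(ValueError, match="empty"):
            apply_manual_process(generate_truth(cfg, ref).iloc[:0], cfg)


class TestScanProcess:
    def test_identity_device_reproduces_truth(self, ref):
        cfg = CohortConfig.noise_free(n_children=25, seed=3)
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        assert len(scan) == 25
        merged = scan.merge(truth, on="child_id")
        np.testing.assert_allclose(merged["stature_cm"], merged["true_stature_cm"])
        np.testing.assert_allclose(merged["muac_cm"], merged["true_muac_cm"])

    def test_mean_difference_converges_to_configured_bias(self, ref):
        """With contamination off, mean(scan - truth) -> scan_bias within 3 SE."""
        n = 1500
        cfg = CohortConfig.noise_free(
            n_children=n,
            seed=8,
            scan_bias_cm={"stature": -0.5, "muac": 0.72},
            scan_noise_sd_cm={"stature": (2.0, 2.0), "muac": (1.0, 1.0)},
        )
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        merged = scan.merge(truth, on="child_id")
        for measure, true_col, bias, sd in [
            ("stature_cm", "true_stature_cm", -0.5, 2.0),
            ("muac_cm", "true_muac_cm", 0.72, 1.0),
        ]:
            diffs = merged[measure] - merged[true_col]
            assert diffs.mean() == pytest.approx(bias, abs=3 * sd / np.sqrt(n))

    def test_total_team_missingness_removes_team(self, ref):
        cfg = CohortConfig.noise_free(
            n_children=60, n_teams=2, seed=10, missingness_prob=(0.0, 1.0)
        )
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        teams = truth.set_index("child_id")["team"]
        assert (teams.loc[scan["child_id"].unique()] == 1).all()
        assert len(scan["child_id"].unique()) == (truth["team"] == 1).sum()

    def test_size_correlated_error_has_positive_sign(self, ref):
        """A positive slope makes scan-minus-truth increase with child size."""
        cfg = CohortConfig.noise_free(
            n_children=800,
            seed=12,
            scan_slope={"stature": 0.3, "muac": 0.0},
            scan_noise_sd_cm={"stature": (1.0, 1.0), "muac": (0.0, 0.0)},
        )
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        merged = scan.merge(truth, on="child_id")
        diffs = merged["stature_cm"] - merged["true_stature_cm"]
        r = np.corrcoef(diffs, merged["true_stature_cm"])[0, 1]
        assert r > 0.5

    def test_sessions_follow_configured_distribution(self, ref):
        cfg = CohortConfig.noise_free(n_children=400, seed=13, sessions_probs=(0.5, 0.5))
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        per_child = scan.groupby("child_id")["session"].max()
        frac_two = (per_child == 2).mean()
        assert frac_two == pytest.approx(0.5, abs=0.08)

    def test_contamination_rate_matches_outlier_prob(self, ref):
        """Adult-contaminant sessions appear at the configured rate (99% binomial)."""
        eps, n = 0.1, 800
        cfg = CohortConfig.noise_free(
            n_children=n,
            seed=14,
            outlier_prob=eps,
            scan_noise_sd_cm={"stature": (0.5, 0.5), "muac": (0.2, 0.2)},
        )
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        # adult contaminants are far taller than any child truth + noise
        contaminated = (scan["stature_cm"] > 135.0).mean()
        se = np.sqrt(eps * (1 - eps) / len(scan))
        assert abs(contaminated - eps) < 2.576 * se

    def test_near_zero_model_emits_junk_below_10cm(self, ref):
        cfg = CohortConfig.noise_free(
            n_children=300, seed=15, outlier_prob=0.2, outlier_model="near-zero"
        )
        truth = generate_truth(cfg, ref)
        scan = apply_scan_process(truth, cfg)
        junk = scan[scan["stature_cm"] < 10.0]
        assert len(junk) > 0
        assert (junk["muac_cm"] < 3.0).all()


class TestIdentifierCorruption:
    @staticmethod
    def _scan_frame(n):
        return pd.DataFrame(
            {
                "child_id": [f"C{i:04d}" for i in range(n)],
                "session": 1,
                "stature_cm": 80.0,
                "muac_cm": 14.0,
            }
        )

    def test_zero_rate_is_identity(self):
        scan = self._scan_frame(10)
        pd.testing.assert_frame_equal(corrupt_identifiers(scan, 0.0, seed=1), scan)

    def test_swaps_are_pairwise_and_preserve_records(self):
        scan = self._scan_frame(50)
        out = corrupt_identifiers(scan, 0.4, seed=2)
        assert len(out) == len(scan)
        assert set(out["child_id"]) == set(scan["child_id"])
        changed = (out["child_id"] != scan["child_id"]).sum()
        assert changed == 2 * round(0.4 * 50 / 2)

    def test_same_seed_same_swaps(self):
        scan = self._scan_frame(30)
        a = corrupt_identifiers(scan, 0.3, seed=7)
        b = corrupt_identifiers(scan, 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_children_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            corrupt_identifiers(self._scan_frame(1), 0.5, seed=1)


class TestGenerateDifferences:
    def test_degenerate_sd_zero(self):
        d = generate_differences(5, 0.72, 0.0, seed=1)
        np.testing.assert_allclose(d, 0.72)

    def test_sample_mean_obeys_clt_bound(self):
        n, mean, sd = 10**6, 0.72, 2.38
        d = generate_differences(n, mean, sd, seed=123)
        assert abs(d.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_same_seed_identical(self):
        a = generate_differences(100, 0.0, 1.0, seed=5)
        b = generate_differences(100, 0.0, 1.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_differences(10, 0.0, -1.0, seed=1)
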