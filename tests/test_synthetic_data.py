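"""Cohort stratification, BP modulation, observer model, waveform ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wearbp.synthetic_data as sd
from wearbp.config import ConfigError, GeneratorConfig


class TestCohort:
    def test_study_scale_stratification(self):
        counts = sd.stratified_counts(120, (0.20, 0.37, 0.26, 0.18))
        assert counts == {"normal": 24, "prehypertension": 44,
                          "stage1": 31, "stage2": 21}
        assert sum(counts.values()) == 120

    def test_minimal_cohort_one_per_class(self):
        counts = sd.stratified_counts(4, (0.25, 0.25, 0.25, 0.25))
        assert all(v == 1 for v in counts.values())

    @pytest.mark.parametrize("n", [7, 40, 121])
    def test_counts_conserve_n(self, n):
        assert sum(sd.stratified_counts(n, (0.20, 0.37, 0.26, 0.18)).values()) == n

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            sd.stratified_counts(10, (0.5, 0.5, 0.5, 0.5))

    def test_determinism(self):
        a = sd.generate_cohort(12, seed=5)
        b = sd.generate_cohort(12, seed=5)
        for sa, sb in zip(a, b):
            assert sa == sb  # dataclass equality covers truth too

    def test_profiles_consistent(self):
        cohort = sd.generate_cohort(30, seed=9)
        assert {s.sex for s in cohort} == {"male", "female"}
        for s in cohort:
            assert 18 <= s.age <= 83
            tr = s.truth
            assert tr.r_to_s1 < tr.r_to_s2 < 60.0 / tr.heart_rate


class TestConditionBP:
    def test_modulation_signs(self, rng):
        """Warm stimulus lowers SBP, cold pressor + walk raises it (in mean)."""
        cfg = GeneratorConfig(subject_sd=(0.0, 0.0), observation_sd=(0.0, 0.0))
        cohort = sd.generate_cohort(8, seed=3, config=cfg)
        for s in cohort:
            warm, _ = sd.simulate_condition_bp(s, "warm_rest", rng, cfg)
            static, _ = sd.simulate_condition_bp(s, "static", rng, cfg)
            cold, _ = sd.simulate_condition_bp(s, "cold_walk", rng, cfg)
            assert warm < static < cold

    def test_unknown_condition(self, clean_cohort, rng):
        with pytest.raises(ValueError, match="condition"):
            sd.simulate_condition_bp(clean_cohort[0], "sprint", rng)

    def test_modulation_means_match_config(self, clean_cohort):
        """Monte-Carlo: empirical condition means within 3 SE of configured."""
        cfg = GeneratorConfig()
        rng = np.random.default_rng(99)
        subject = clean_cohort[0]
        n = 1000
        for cond in sd.CONDITIONS:
            draws = np.array([
                sd.simulate_condition_bp(subject, cond, rng, cfg)[0]
                for _ in range(n)
            ])
            expected = subject.truth.condition_bp[cond][0]
            se = cfg.observation_sd[0] / np.sqrt(n)
            assert abs(draws.mean() - expected) < 3 * se

    def test_pulse_pressure_floor(self, clean_cohort, rng):
        cfg = GeneratorConfig(observation_sd=(12.0, 12.0))
        for _ in range(200):
            sbp, dbp = sd.simulate_condition_bp(clean_cohort[3], "rest", rng, cfg)
            assert sbp - dbp >= 15


class TestObservers:
    def test_noise_free_reads_truth(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(observer_noise_sd=0.0)
        r = sd.simulate_observers(120, 80, rng, cfg)
        assert r["obs1_sbp"] == r["obs2_sbp"] == 120

    def test_grid_rounding_half_to_even(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(observer_noise_sd=0.0)
        assert sd.simulate_observers(121, 80, rng, cfg)["obs1_sbp"] == 120
        assert sd.simulate_observers(123, 80, rng, cfg)["obs1_sbp"] == 124

    def test_all_readings_on_grid(self, rng):
        for _ in range(50):
            r = sd.simulate_observers(133.3, 84.7, rng)
            assert all(v % 2 == 0 for v in r.values())

    def test_disagreement_rate_matches_analytic(self):
        """P(|obs1-obs2| > 4) for rounded-normal readings vs enumeration."""
        true, s = 121.0, 2.0
        grid = np.arange(80, 162, 2, dtype=float)
        cell = stats.norm.cdf((grid + 1 - true) / s) - stats.norm.cdf((grid - 1 - true) / s)
        diff_gt4 = 0.0
        for i, pi in enumerate(cell):
            for j, pj in enumerate(cell):
                if abs(grid[i] - grid[j]) > 4:
                    diff_gt4 += pi * pj
        rng = np.random.default_rng(7)
        n = 10_000
        cfg = GeneratorConfig(observer_noise_sd=s)
        draws = np.array([
            [r["obs1_sbp"], r["obs2_sbp"]]
            for r in (sd.simulate_observers(true, 80, rng, cfg) for _ in range(n))
        ])
        frac = np.mean(np.abs(draws[:, 0] - draws[:, 1]) > 4)
        se = np.sqrt(diff_gt4 * (1 - diff_gt4) / n)
        assert abs(frac - diff_gt4) < 3 * se

    def test_requires_positive_pressures(self, rng):
        with pytest.raises(ValueError):
            sd.simulate_observers(-5, 80, rng)


class TestWaveforms:
    def test_s2_burst_placement(self):
        """Noise-free synthesis: S2 energy is centred at R + r_to_s2."""
        cfg = GeneratorConfig(coupling=sd.CouplingConfig(enabled=False))
        cohort = sd.generate_cohort(4, seed=13, config=cfg)
        subject = cohort[0]
        subject.truth.condition_bp = {c: (120.0, 80.0) for c in sd.CONDITIONS}
        subject.truth.heart_rate = 60.0
        subject.truth.r_to_s2 = 0.300
        protocol = sd.default_protocol(1)
        session = sd.synthesize_recording(subject, protocol, seed=1, config=cfg)
        pcg = session.recording.channels["pcg"]
        ecg = session.recording.channels["ecg1"]
        # locate one R peak and check the S2 burst centre 0.300 s later
        r_idx = int(np.argmax(ecg.samples[:int(2 * ecg.fs)]))
        s2_centre = r_idx + int(0.300 * pcg.fs)
        window = np.abs(pcg.samples[s2_centre - 50:s2_centre + 51])
        assert abs(int(np.argmax(window)) - 50) <= 1

    def test_s2_timing_decreases_with_sbp(self):
        """Planted coupling: higher SBP gives an earlier S2."""
        cfg = GeneratorConfig()
        assert (sd.coupled_r_to_s2(160, cfg.coupling)
                < sd.coupled_r_to_s2(110, cfg.coupling))

    def test_protocol_too_long_rejected(self, clean_cohort):
        with pytest.raises(ConfigError, match="duration"):
            sd.synthesize_recording(clean_cohort[0], sd.default_protocol(3),
                                    seed=1, max_duration_s=100.0)

    def test_observation_spacing(self):
        protocol = sd.default_protocol(3)
        times = [t for _, t in protocol.schedule()]
        assert np.all(np.diff(times) >= 60.0)
        per_block = [b.n_observations for b in protocol.blocks]
        assert per_block == [3, 3, 3, 3]  # three readings after each activity

    def test_recording_determinism(self, clean_cohort):
        protocol = sd.default_protocol(1)
        a = sd.synthesize_recording(clean_cohort[0], protocol, seed=4)
        b = sd.synthesize_recording(clean_cohort[0], protocol, seed=4)
        for name in a.recording.channels:
            assert np.array_equal(a.recording.channels[name].samples,
                                  b.recording.channels[name].samples)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestFeatureLevelGenerator:
    def test_shape_and_determinism(self):
        a = sd.simulate_feature_dataset(6, 8, seed=2)
        b = sd.simulate_feature_dataset(6, 8, seed=2)
        assert len(a) == 48
        pd.testing.assert_frame_equal(a, b)

    def test_references_reconciled(self):
        df = sd.simulate_feature_dataset(6, 8, seed=2)
        # reconciled means of 2-mmHg readings land on the 1-mmHg grid
        assert np.allclose(df["sbp_ref"] % 1, 0)
        assert (df["sbp_ref"] - df["dbp_ref"]).min() > 0

    def test_null_mode_features_independent_of_bp(self):
        """With coupling off, S2 timing carries no information about SBP
        (permutation correlation test, alpha = 0.01, 50 datasets).

        One observation per subject: rows are then exchangeable, which the
        permutation null requires (within-subject clustering would not be).
        """
        cfg = GeneratorConfig()
        cfg.coupling.enabled = False
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(50):
            df = sd.simulate_feature_dataset(40, 1, seed=seed, config=cfg)
            x = df["r_to_s2"].to_numpy()
            y = df["true_sbp"].to_numpy()
            obs = abs(np.corrcoef(x, y)[0, 1])
            perm = np.array([
                abs(np.corrcoef(x, rng.permutation(y))[0, 1])
                for _ in range(200)
            ])
            p = (1 + np.sum(perm >= obs)) / 201
            hits += p <= 0.01
        assert hits <= 4  # ~Binomial(50, 0.01) upper tail

    def test_coupled_mode_correlation_present(self):
        df = sd.simulate_feature_dataset(20, 10, seed=3)
        r = np.corrcoef(df["r_to_s2"], df["true_sbp"])[0, 1]
        assert r < -0.5  # planted negative coupling dominates
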