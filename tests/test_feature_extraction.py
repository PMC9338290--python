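"""R peaks, ensemble averaging, heart sounds, impedance, feature vectors."""

import numpy as np
import pytest

import wearbp.feature_extraction as fe
import wearbp.preprocessing as pp
from wearbp.config import ConfigError, FeatureConfig


def synth_ecg(fs=500.0, duration=60.0, hr=60.0, qrs=0.09, noise_sd=0.0, seed=0):
    """Stand-alone sum-of-Gaussians ECG with known R times."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    rr = 60.0 / hr
    r_times = np.arange(0.5, duration - 0.5, rr)
    sigma = qrs / (2 * np.sqrt(2 * np.log(10)))
    for r in r_times:
        x += 0.12 * np.exp(-0.5 * ((t - r + 0.16) / 0.02) ** 2)
        x += 1.00 * np.exp(-0.5 * ((t - r) / sigma) ** 2)
        x += 0.25 * np.exp(-0.5 * ((t - r - 0.30) / 0.055) ** 2)
    if noise_sd:
        x = x + rng.normal(0, noise_sd, n)
    return x, r_times


class TestRPeaks:
    def test_clean_recovery_within_one_sample(self):
        fs = 500.0
        ecg, planted = synth_ecg(fs=fs)
        ann = fe.detect_r_peaks(ecg, fs)
        assert abs(len(ann.r_times) - len(planted)) <= 1
        for r in ann.r_times:
            assert np.min(np.abs(planted - r)) <= 1.0 / fs
        assert ann.mean_interbeat_interval == pytest.approx(1.0, abs=2 / fs)

    def test_zero_signal_rejected(self):
        with pytest.raises(fe.WindowRejectionError):
            fe.detect_r_peaks(np.zeros(30_000), 500.0)

    def test_noisy_recovery(self):
        """SNR 10 dB additive white noise: >= 99% of beats within 2 samples."""
        fs = 500.0
        recovered = total = 0
        for seed in range(10):
            clean, planted = synth_ecg(fs=fs, seed=seed)
            power = np.mean(clean ** 2)
            noise_sd = np.sqrt(power / 10.0)  # SNR 10 dB
            ecg = clean + np.random.default_rng(seed).normal(0, noise_sd, len(clean))
            ann = fe.detect_r_peaks(ecg, fs)
            total += len(planted)
            for r in planted:
                if np.min(np.abs(ann.r_times - r)) <= 2.0 / fs:
                    recovered += 1
        assert recovered / total >= 0.99

    def test_too_short_signal(self):
        with pytest.raises(fe.WindowRejectionError):
            fe.detect_r_peaks(np.ones(100), 500.0)


class TestEnsembleAverage:
    def _beats(self, fs=500.0, n_beats=30, rr=0.8, seed=0, noise_sd=0.0):
        rng = np.random.default_rng(seed)
        n = int((n_beats + 1) * rr * fs)
        t = np.arange(n) / fs
        r_times = 0.4 + np.arange(n_beats) * rr
        x = np.zeros(n)
        for r in r_times:
            x += np.exp(-0.5 * ((t - r) / 0.02) ** 2)
        if noise_sd:
            x = x + rng.normal(0, noise_sd, n)
        return x, r_times

    def test_identical_beats_reproduced(self):
        fs = 500.0
        x, r_times = self._beats(fs)
        ens = fe.ensemble_average(x, fs, r_times, "ecg")
        ri = int(round(r_times[3] * fs))
        single = x[ri - ens.r_index: ri - ens.r_index + len(ens.beat)]
        assert np.allclose(ens.beat, single, atol=1e-9)
        assert ens.n_beats_averaged >= 28

    def test_noise_suppression_scales_with_beats(self):
        fs, sd, n_beats = 500.0, 0.2, 50
        x, r_times = self._beats(fs, n_beats=n_beats, noise_sd=sd, seed=3)
        clean, _ = self._beats(fs, n_beats=n_beats)
        ens = fe.ensemble_average(x, fs, r_times, "ecg")
        ens_clean = fe.ensemble_average(clean, fs, r_times, "ecg")
        residual_sd = np.std(ens.beat - ens_clean.beat)
        expected = sd / np.sqrt(ens.n_beats_averaged)
        assert residual_sd == pytest.approx(expected, rel=0.2)

    def test_corrupted_beat_excluded(self):
        fs = 500.0
        x, r_times = self._beats(fs, n_beats=60)
        clean_ens = fe.ensemble_average(x, fs, r_times, "ecg")
        corrupted = x.copy()
        ri = int(round(r_times[20] * fs))
        rng = np.random.default_rng(5)
        corrupted[ri - 70:ri + 300] = rng.normal(0, 5.0, 370)  # inside this beat's frame
        ens = fe.ensemble_average(corrupted, fs, r_times, "ecg")
        assert ens.n_beats_averaged == clean_ens.n_beats_averaged - 1
        assert np.allclose(ens.beat, clean_ens.beat, atol=0.02)

    def test_too_few_beats_rejected(self):
        x, r_times = self._beats(n_beats=30)
        with pytest.raises(fe.WindowRejectionError):
            fe.ensemble_average(x, 500.0, r_times[:3], "ecg")


def synth_pcg_ensemble(fs=500.0, rr=1.0, s1=0.04, s2=0.30, a1=0.75, a2=0.5):
    """One-beat PCG frame shaped like the ensemble output (R at 20% of RR)."""
    length = int(rr * fs)
    pre = int(round(0.2 * length))
    t = (np.arange(length) - pre) / fs
    x = np.zeros(length)
    if a1:
        env1 = np.exp(-0.5 * ((t - s1) / 0.018) ** 2)
        x += a1 * env1 * np.cos(2 * np.pi * 30.0 * (t - s1))
    if a2:
        env2 = np.exp(-0.5 * ((t - s2) / 0.014) ** 2)
        x += a2 * env2 * np.cos(2 * np.pi * 70.0 * (t - s2))
    return fe.EnsembleBeat(x, fs, pre, rr, 40)


class TestHeartSounds:
    def test_planted_times_recovered(self):
        ens = synth_pcg_ensemble()
        out = fe.extract_s1_s2(ens)
        assert out["s1_time"] == pytest.approx(0.04, abs=1.0 / ens.fs)
        assert out["s2_time"] == pytest.approx(0.30, abs=1.0 / ens.fs)

    def test_absent_s2_flagged_s1_kept(self):
        ens = synth_pcg_ensemble(a2=0.0)
        out = fe.extract_s1_s2(ens)
        assert np.isnan(out["s2_time"]) and np.isnan(out["s2_rms"])
        assert out["s1_time"] == pytest.approx(0.04, abs=1.0 / ens.fs)

    def test_amplitude_homogeneity(self):
        a = fe.extract_s1_s2(synth_pcg_ensemble())
        ens2 = synth_pcg_ensemble()
        ens2.beat *= 2.0
        b = fe.extract_s1_s2(ens2)
        assert b["s1_rms"] == pytest.approx(2 * a["s1_rms"], rel=1e-9)
        assert b["s2_rms"] == pytest.approx(2 * a["s2_rms"], rel=1e-9)
        assert b["s1s2_rms_ratio"] == pytest.approx(a["s1s2_rms_ratio"], rel=1e-9)
        assert b["s1_time"] == a["s1_time"]


class TestBandFeatures:
    def test_pure_tone_lands_in_mid_band(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        amp = 0.7
        tone = amp * np.sqrt(2) * np.sin(2 * np.pi * 75.0 * t)  # RMS = amp
        out = fe.band_features(tone, fs)
        assert out["s_mid"] == pytest.approx(amp, rel=0.05)
        assert out["s_low"] < 0.05 * amp
        assert out["s_high"] < 0.05 * amp

    def test_zero_signal(self):
        out = fe.band_features(np.zeros(5000), 500.0)
        assert out["s_low"] == out["s_mid"] == out["s_high"] == 0.0

    def test_band_power_bounded_by_total(self, rng):
        x = rng.normal(size=10_000)
        out = fe.band_features(x, 500.0)
        total = np.mean(x ** 2)
        assert out["s_low"] ** 2 + out["s_mid"] ** 2 + out["s_high"] ** 2 <= total

    def test_band_above_nyquist_rejected(self):
        cfg = FeatureConfig(band_high=(100.0, 300.0))
        with pytest.raises(ConfigError, match="Nyquist"):
            fe.band_features(np.zeros(5000), 500.0, cfg)


class TestImpedanceFeatures:
    def test_planted_rate_and_tidal_volume(self):
        fs, z0, amp, bpm = 50.0, 30.0, 1.2, 15.0
        t = np.arange(int(60 * fs)) / fs
        x = z0 + amp * np.sin(2 * np.pi * (bpm / 60.0) * t)
        out = fe.impedance_features(x, x, fs)
        assert out["respiration_rate_1"] == pytest.approx(bpm, abs=0.5)
        assert out["relative_tidal_volume_1"] == pytest.approx(2 * amp / z0, rel=0.05)
        assert out["mean_impedance"] == pytest.approx(z0, rel=0.01)

    def test_constant_signal_rate_missing(self):
        x = np.full(3000, 30.0)
        out = fe.impedance_features(x, x, 50.0)
        assert np.isnan(out["respiration_rate_1"])
        assert out["relative_tidal_volume_1"] == 0.0


class TestFeatureVector:
    def _window(self, session, mask, k=2):
        obs = session.observations[k]
        w = pp.associate_window(mask, session.recording, obs)
        assert isinstance(w, pp.AnalysisWindow)
        return w, obs

    def test_clean_window_no_missing(self, clean_session, clean_mask):
        w, _ = self._window(clean_session, clean_mask)
        fv = fe.build_feature_vector(w, clean_session.subject)
        assert not any(fv.missing.values())
        assert set(fv.values) == set(fe.FEATURE_REGISTRY)

    def test_zeroed_pcg_flags_heart_sounds_only(self, clean_session, clean_mask):
        w, _ = self._window(clean_session, clean_mask)
        w.channels["pcg"].samples = np.zeros_like(w.channels["pcg"].samples)
        fv = fe.build_feature_vector(w, clean_session.subject)
        for name in ("r_to_s1", "r_to_s2", "s1_rms", "s2_rms", "s1s2_rms_ratio"):
            assert fv.missing[name]
        for name in ("mean_interbeat_interval", "respiration_rate_1",
                     "relative_tidal_volume_1", "qrs_duration"):
            assert not fv.missing[name]

    def test_deterministic(self, clean_session, clean_mask):
        w, _ = self._window(clean_session, clean_mask)
        a = fe.build_feature_vector(w, clean_session.subject)
        b = fe.build_feature_vector(w, clean_session.subject)
        assert a.values == b.values and a.missing == b.missing

    def test_scale_invariance_of_timing(self, clean_session, clean_mask):
        w, _ = self._window(clean_session, clean_mask)
        fv = fe.build_feature_vector(w, clean_session.subject)
        for name, ch in w.channels.items():
            ch.samples = ch.samples * 3.0
        scaled = fe.build_feature_vector(w, clean_session.subject)
        for name in ("r_to_s1", "r_to_s2", "mean_interbeat_interval",
                     "qrs_duration", "respiration_rate_1", "s1s2_rms_ratio",
                     "relative_tidal_volume_1"):
            assert scaled.values[name] == pytest.approx(fv.values[name], rel=1e-6)
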