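"""Per-window feature extraction: ECG, heart sounds, impedance, demographics.

The feature set mirrors what a multiparametric wearable can measure during a
cuff reading: R-peak timing and interbeat intervals from the ECG; S1/S2
timing relative to R, RMS amplitudes and spectral band energies from the
ensemble-averaged phonocardiogram (systolic time intervals are the
physiological link to blood pressure); respiration rate and relative tidal
volume from each thoracic-impedance channel; and subject demographics.

All features are computed on a 60-s analysis window.  Individual features
that cannot be measured are flagged missing (never silent NaN); a window
whose signal features are mostly missing is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import ConfigError, FeatureConfig

#: canonical feature registry: column order of the model matrix.
SIGNAL_FEATURES = [
    "respiration_rate_1", "respiration_rate_2",
    "relative_tidal_volume_1", "relative_tidal_volume_2",
    "mean_impedance",
    "r_to_s1", "r_to_s2", "mean_interbeat_interval",
    "s1s2_rms_ratio", "s1_rms", "s2_rms",
    "s_low", "s_mid", "s_high", "s1_low",
    "qrs_duration",
]
DEMOGRAPHIC_FEATURES = ["age", "sex_male", "height", "weight"]
FEATURE_REGISTRY = SIGNAL_FEATURES + DEMOGRAPHIC_FEATURES


class WindowRejectionError(ValueError):
    """The window cannot yield a usable feature vector."""


@dataclass
class BeatAnnotations:
    r_times: np.ndarray  # s, within the window
    rr_intervals: np.ndarray  # screened successive differences, s
    mean_interbeat_interval: float  # s
    qrs_duration: float | None = None  # filled from the ensemble beat


@dataclass
class EnsembleBeat:
    """Beat-aligned pointwise average over one median RR interval."""

    beat: np.ndarray
    fs: float
    r_index: int  # sample index of the R origin within `beat`
    median_rr: float  # s
    n_beats_averaged: int


@dataclass
class FeatureVector:
    observation_id: str
    values: dict[str, float]
    missing: dict[str, bool]

    def to_row(self) -> dict[str, float]:
        row = {"observation_id": self.observation_id}
        for name in FEATURE_REGISTRY:
            row[name] = self.values.get(name, np.nan)
            row[f"{name}__missing"] = float(self.missing.get(name, False))
        return row


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if hi >= nyq:
        raise ConfigError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks_raw(ecg: np.ndarray, fs: float,
                       refractory_s: float = 0.25) -> np.ndarray:
    """Detect R-peak times (s) with a derivative-energy detector.

    Band-pass 5–25 Hz, differentiate, square, moving-window integrate
    (150 ms), adaptive threshold with a 250-ms refractory period; candidate
    peaks are then refined to the local extremum of the raw ECG.  Raises
    ``ValueError`` when no beats are detectable.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(10 * fs):
        raise ValueError("need at least 10 s of ECG")
    filtered = _bandpass(ecg, fs, 5.0, 25.0, order=2)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(0.150 * fs))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = np.percentile(integrated, 99)
    if peak_level <= 0:
        raise ValueError("no beats detectable (flat signal)")
    threshold = 0.25 * peak_level
    locs, _ = sps.find_peaks(integrated, height=threshold,
                             distance=max(1, int(refractory_s * fs)))
    if len(locs) == 0:
        raise ValueError("no beats detected")
    # refine to the signal extremum near each candidate; a short symmetric
    # moving average suppresses noise without biasing a symmetric peak
    half = int(0.08 * fs)
    k = max(1, int(0.03 * fs) | 1)
    smoothed = np.convolve(ecg, np.ones(k) / k, mode="same")
    refined = []
    for loc in locs:
        i0, i1 = max(0, loc - half), min(len(ecg), loc + half + 1)
        seg = smoothed[i0:i1]
        refined.append(i0 + int(np.argmax(np.abs(seg - np.median(seg)))))
    refined = np.unique(refined)
    # drop refined peaks closer than the refractory period (keep the larger)
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) < refractory_s * fs:
            if abs(ecg[idx]) > abs(ecg[keep[-1]]):
                keep[-1] = idx
        else:
            keep.append(idx)
    return np.asarray(keep, dtype=float) / fs


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   config: FeatureConfig | None = None,
                   rr_bounds: tuple[float, float] = (0.3, 2.0)) -> BeatAnnotations:
    """R peaks plus screened RR intervals; rejects windows with < 5 beats."""
    config = config or FeatureConfig()
    try:
        r_times = detect_r_peaks_raw(ecg, fs)
    except ValueError as e:
        raise WindowRejectionError(f"r_peak_detection_failed: {e}") from e
    if len(r_times) < config.min_beats:
        raise WindowRejectionError("too_few_beats")
    rr = np.diff(r_times)
    rr = rr[(rr >= rr_bounds[0]) & (rr <= rr_bounds[1])]
    if len(rr) < config.min_beats - 1:
        raise WindowRejectionError("too_few_plausible_rr_intervals")
    return BeatAnnotations(
        r_times=r_times,
        rr_intervals=rr,
        mean_interbeat_interval=float(rr.mean()),
    )


# --------------------------------------------------------------------------
# ensemble averaging
# --------------------------------------------------------------------------

def ensemble_average(sig: np.ndarray, fs: float, r_times: np.ndarray,
                     mode: str = "ecg",
                     config: FeatureConfig | None = None) -> EnsembleBeat:
    """Beat-aligned pointwise mean over one median RR interval.

    Beats are aligned at R; the beat frame spans 20% of the median RR before
    R to 80% after it, so both the QRS flanks and the S1/S2 sounds lie inside
    the frame.  Outlier beats (correlation with the running mean < 0.5) are
    excluded before the final average; fewer than five surviving beats is a
    rejection.
    """
    if mode not in ("ecg", "pcg"):
        raise ValueError(f"unknown ensemble mode {mode!r}")
    config = config or FeatureConfig()
    sig = np.asarray(sig, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < config.min_beats:
        raise WindowRejectionError("too_few_beats")
    median_rr = float(np.median(np.diff(r_times)))
    length = int(round(median_rr * fs))
    pre = int(round(0.2 * length))
    post = length - pre

    segments = []
    for r in r_times:
        ri = int(round(r * fs))
        if ri - pre < 0 or ri + post > len(sig):
            continue
        segments.append(sig[ri - pre:ri + post])
    if len(segments) < config.min_beats:
        raise WindowRejectionError("too_few_complete_beats")
    beats = np.asarray(segments)

    kept = np.ones(len(beats), dtype=bool)
    for _ in range(2):  # two passes: mean stabilizes after outlier removal
        template = beats[kept].mean(axis=0)
        tz = template - template.mean()
        tnorm = np.linalg.norm(tz)
        if tnorm == 0:
            break
        for i, b in enumerate(beats):
            bz = b - b.mean()
            bnorm = np.linalg.norm(bz)
            corr = 1.0 if bnorm == 0 and tnorm == 0 else (
                0.0 if bnorm == 0 else float(bz @ tz / (bnorm * tnorm)))
            kept[i] = corr >= config.beat_corr_min
        if kept.sum() < config.min_beats:
            raise WindowRejectionError("too_few_consistent_beats")
    ensemble = beats[kept].mean(axis=0)
    return EnsembleBeat(ensemble, fs, pre, median_rr, int(kept.sum()))


def measure_qrs_duration(ens: EnsembleBeat,
                         threshold: float = 0.10) -> float:
    """QRS width: the contiguous run around R where |ECG| exceeds
    ``threshold`` x the R amplitude."""
    beat = ens.beat
    r_amp = abs(beat[ens.r_index])
    if r_amp == 0:
        return float("nan")
    above = np.abs(beat) > threshold * r_amp
    i0 = ens.r_index
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = ens.r_index
    while i1 < len(beat) - 1 and above[i1 + 1]:
        i1 += 1
    return (i1 - i0 + 1) / ens.fs


# --------------------------------------------------------------------------
# heart sounds
# --------------------------------------------------------------------------

def _envelope(x: np.ndarray, fs: float, smooth_s: float = 0.011) -> np.ndarray:
    """Amplitude envelope (analytic magnitude, lightly smoothed)."""
    env = np.abs(sps.hilbert(x))
    win = max(1, int(smooth_s * fs) | 1)  # odd length: symmetric, peak-preserving
    kernel = np.hanning(win + 2)[1:-1]
    return np.convolve(env, kernel / kernel.sum(), mode="same")


def extract_s1_s2(ens: EnsembleBeat,
                  config: FeatureConfig | None = None) -> dict[str, float]:
    """S1/S2 timing and RMS from the ensemble-averaged phonocardiogram.

    S1 is the strongest envelope peak within (0, 0.25*RR] after R, S2 within
    (0.25*RR, 0.6*RR]; each sound's RMS is taken over +/-40 ms around its
    envelope peak.  A region with no peak above the envelope noise floor
    (3x the envelope median, and at least 5% of the strongest sound) yields
    NaN for that sound's features.
    """
    config = config or FeatureConfig()
    fs = ens.fs
    pcg = _bandpass_safe(ens.beat, fs, config.band_low[0], config.band_high[1])
    env = _envelope(pcg, fs)
    floor = max(3.0 * np.median(env), 0.05 * env.max(initial=0.0)) + 1e-12
    rr_samples = ens.median_rr * fs

    out: dict[str, float] = {}
    half = int(config.s_window_ms / 1000.0 * fs)
    for name, (f0, f1) in (("s1", config.s1_region), ("s2", config.s2_region)):
        i0 = ens.r_index + max(1, int(f0 * rr_samples))
        i1 = ens.r_index + int(f1 * rr_samples)
        i1 = min(i1, len(env))
        if i1 <= i0 or env[i0:i1].max(initial=0.0) < floor:
            out[f"{name}_time"] = float("nan")
            out[f"{name}_rms"] = float("nan")
            continue
        peak = i0 + int(np.argmax(env[i0:i1]))
        seg = pcg[max(0, peak - half):peak + half + 1]
        out[f"{name}_time"] = (peak - ens.r_index) / fs
        out[f"{name}_rms"] = float(np.sqrt(np.mean(seg ** 2)))
        out[f"{name}_index"] = peak
    s1, s2 = out.get("s1_rms"), out.get("s2_rms")
    out["s1s2_rms_ratio"] = (
        s1 / s2 if s1 is not None and s2 is not None and s2 and not math.isnan(s1)
        and not math.isnan(s2) else float("nan")
    )
    return out


def _bandpass_safe(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)  # keep the analysis band below Nyquist
    return _bandpass(x, fs, lo, hi)


def band_features(pcg_window: np.ndarray, fs: float,
                  config: FeatureConfig | None = None,
                  s1_index: int | None = None) -> dict[str, float]:
    """RMS of the PCG in the low/mid/high bands, plus S1-gated low-band RMS.

    ``s1_index`` is the S1 envelope-peak sample within ``pcg_window``; when
    absent, ``s1_low`` is flagged missing.
    """
    config = config or FeatureConfig()
    nyq = fs / 2.0
    out = {}
    for name, (lo, hi) in (("s_low", config.band_low), ("s_mid", config.band_mid),
                           ("s_high", config.band_high)):
        if hi >= nyq:
            raise ConfigError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
        filtered = _bandpass(pcg_window, fs, lo, hi)
        out[name] = float(np.sqrt(np.mean(filtered ** 2)))
    if s1_index is None:
        out["s1_low"] = float("nan")
    else:
        half = int(config.s_window_ms / 1000.0 * fs)
        low = _bandpass(pcg_window, fs, *config.band_low)
        seg = low[max(0, s1_index - half):s1_index + half + 1]
        out["s1_low"] = float(np.sqrt(np.mean(seg ** 2)))
    return out


# --------------------------------------------------------------------------
# impedance pneumography
# --------------------------------------------------------------------------

def _respiration_rate(x: np.ndarray, fs: float,
                      band: tuple[float, float]) -> float:
    """Dominant spectral frequency in the respiratory band, breaths/min.

    Zero-padded periodogram with parabolic peak interpolation; NaN when no
    peak stands 3x above the in-band median amplitude.
    """
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(n * 4)))
    spec = np.abs(np.fft.rfft(x * np.hanning(n), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return float("nan")
    sub = spec[in_band]
    if sub.max(initial=0.0) < 3.0 * np.median(sub) + 1e-12:
        return float("nan")
    k = int(np.argmax(sub))
    base = np.flatnonzero(in_band)[0]
    i = base + k
    # parabolic interpolation around the bin peak
    if 0 < i < len(spec) - 1:
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f = (i + delta) * fs / nfft
    return 60.0 * f


def _tidal_excursion(x: np.ndarray, fs: float) -> float:
    """Mean peak-to-trough respiratory excursion of an impedance trace."""
    centred = x - np.mean(x)
    # isolate the respiratory component (cardiac ripple sits above ~0.9 Hz)
    nyq = fs / 2.0
    sos = sps.butter(4, 0.7 / nyq, btype="low", output="sos")
    resp = sps.sosfiltfilt(sos, centred)
    prom = 0.3 * np.std(resp)
    if prom <= 0:
        return 0.0
    peaks, _ = sps.find_peaks(resp, prominence=prom)
    troughs, _ = sps.find_peaks(-resp, prominence=prom)
    if len(peaks) == 0 or len(troughs) == 0:
        return 0.0
    return float(resp[peaks].mean() - resp[troughs].mean())


def impedance_features(imp1: np.ndarray, imp2: np.ndarray, fs: float,
                       config: FeatureConfig | None = None) -> dict[str, float]:
    """Respiration rate and relative tidal volume per channel, mean impedance.

    Relative tidal volume is the mean peak-to-trough respiratory excursion
    divided by the channel's mean impedance level — a dimensionless surrogate
    for tidal volume.
    """
    config = config or FeatureConfig()
    out = {}
    for k, x in (("1", np.asarray(imp1, float)), ("2", np.asarray(imp2, float))):
        rate = _respiration_rate(x, fs, config.resp_band_hz)
        out[f"respiration_rate_{k}"] = rate
        level = float(np.mean(x))
        out[f"relative_tidal_volume_{k}"] = (
            _tidal_excursion(x, fs) / level if level != 0 else float("nan")
        )
    out["mean_impedance"] = float(np.mean(imp1))
    return out


# --------------------------------------------------------------------------
# the full vector
# --------------------------------------------------------------------------

def build_feature_vector(window, subject,
                         config: FeatureConfig | None = None) -> FeatureVector:
    """Compute the registry features for one analysis window.

    ``window`` is a :class:`wearbp.preprocessing.AnalysisWindow`; ``subject``
    a :class:`wearbp.synthetic_data.SubjectProfile` (any object with age,
    sex, height, weight works).  Features that cannot be measured are
    flagged; the observation is dropped when more than 30% of signal
    features are missing.
    """
    config = config or FeatureConfig()
    values: dict[str, float] = {}
    missing: dict[str, bool] = {}

    def put(name: str, value: float) -> None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            values[name] = float("nan")
            missing[name] = True
        else:
            values[name] = float(value)
            missing[name] = False

    ecg = window.channels["ecg1"]
    pcg = window.channels["pcg"]
    imp1 = window.channels["imp1"]
    imp2 = window.channels["imp2"]

    beats = detect_r_peaks(ecg.samples, ecg.fs, config)
    put("mean_interbeat_interval", beats.mean_interbeat_interval)

    ens_ecg = ensemble_average(ecg.samples, ecg.fs, beats.r_times, "ecg", config)
    put("qrs_duration", measure_qrs_duration(ens_ecg, config.qrs_threshold))

    # PCG ensembling uses the ECG R times (cross-signal alignment)
    try:
        ens_pcg = ensemble_average(pcg.samples, pcg.fs, beats.r_times, "pcg", config)
        sounds = extract_s1_s2(ens_pcg, config)
    except WindowRejectionError:
        sounds = {}
    put("r_to_s1", sounds.get("s1_time", float("nan")))
    put("r_to_s2", sounds.get("s2_time", float("nan")))
    put("s1_rms", sounds.get("s1_rms", float("nan")))
    put("s2_rms", sounds.get("s2_rms", float("nan")))
    put("s1s2_rms_ratio", sounds.get("s1s2_rms_ratio", float("nan")))

    # overall band RMS on the whole window; S1-gated low band on the ensemble
    bands = band_features(pcg.samples, pcg.fs, config, s1_index=None)
    if "s1_index" in sounds:
        ens_bands = band_features(ens_pcg.beat, pcg.fs, config,
                                  s1_index=int(sounds["s1_index"]))
        bands["s1_low"] = ens_bands["s1_low"]
    for name in ("s_low", "s_mid", "s_high", "s1_low"):
        put(name, bands.get(name, float("nan")))

    imps = impedance_features(imp1.samples, imp2.samples, imp1.fs, config)
    for name in ("respiration_rate_1", "respiration_rate_2",
                 "relative_tidal_volume_1", "relative_tidal_volume_2",
                 "mean_impedance"):
        put(name, imps[name])

    n_missing = sum(missing[n] for n in SIGNAL_FEATURES)
    if n_missing > config.max_missing_fraction * len(SIGNAL_FEATURES):
        raise WindowRejectionError("too_many_missing_features")

    put("age", float(subject.age))
    put("sex_male", 1.0 if subject.sex == "male" else 0.0)
    put("height", float(subject.height))
    put("weight", float(subject.weight))

    return FeatureVector(window.observation.observation_id, values, missing)
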