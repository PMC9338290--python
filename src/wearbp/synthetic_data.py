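"""Synthetic study generator with known ground-truth hemodynamics.

Emulates the structure of a cuffless-BP validation study: a cohort stratified
over the four JNC-7 classes, a per-subject session protocol in which
activities modulate blood pressure (warm stimulus lowers it, cold pressor +
walking raise it), dual-observer sphygmomanometer readings rounded to the
2-mmHg grid, a noisier sequential wrist-cuff column, and raw multichannel
waveforms (2x ECG, phonocardiogram, 2x thoracic impedance, activity).

The waveform models are deliberately simple closed forms whose ground truth
is exactly known: a sum-of-Gaussians ECG beat, Gaussian-windowed tone bursts
for the S1/S2 heart sounds, and a sinusoidal respiratory impedance signal.
A configurable coupling plants the signal<->BP relationships the downstream
models are meant to find (S2 timing decreasing with SBP, S1/S2 amplitude
ratio tracking DBP); with coupling disabled the generator is a null model in
which signal features are independent of BP.

Two generation paths exist:

* :func:`synthesize_recording` — full raw waveforms, for exercising quality
  screening, window association and signal feature extraction;
* :func:`simulate_feature_dataset` — features drawn directly from the planted
  hemodynamics, for Monte-Carlo studies of feature selection, model
  superiority and bootstrap behaviour at many seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, CouplingConfig, GeneratorConfig
from .reference_bp import BP_CLASSES, classify_jnc7
from .signal_io import BPObservation, Channel, MultichannelRecording

CONDITIONS = ("static", "warm_rest", "cold_walk", "rest")

#: entry-BP sampling ranges per class, chosen to lie strictly inside the
#: JNC-7 cells so the class label is consistent by construction.
_CLASS_BP_RANGES = {
    "normal": ((100, 118), (62, 78)),
    "prehypertension": ((122, 138), (72, 88)),
    "stage1": ((140, 158), (84, 98)),
    "stage2": ((160, 185), (92, 114)),
}
_CLASS_AGE_RANGES = {
    "normal": (18, 55),
    "prehypertension": (25, 70),
    "stage1": (35, 78),
    "stage2": (45, 83),
}


@dataclass
class GroundTruthHemodynamics:
    """The planted physiology one subject's signals are synthesized from."""

    condition_bp: dict[str, tuple[float, float]]  # condition -> (SBP, DBP)
    heart_rate: float  # beats/min
    respiration_rate: float  # breaths/min
    r_to_s1: float  # s
    r_to_s2: float  # s, at the subject's entry SBP
    qrs_duration: float  # s
    tidal_amplitude: float  # ohm
    baseline_impedance: float  # ohm

    def __post_init__(self) -> None:
        if not (0 < self.r_to_s1 < self.r_to_s2 < 60.0 / self.heart_rate):
            raise ValueError("require 0 < r_to_s1 < r_to_s2 < beat period")
        for c, (sbp, dbp) in self.condition_bp.items():
            if sbp - dbp < 15:
                raise ValueError(f"SBP - DBP < 15 mmHg for condition {c}")


@dataclass
class SubjectProfile:
    subject_id: str
    age: int
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    entry_sbp: float
    entry_dbp: float
    bp_class: str
    truth: GroundTruthHemodynamics | None = None

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 83:
            raise ValueError(f"age {self.age} outside [18, 83]")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if classify_jnc7(self.entry_sbp, self.entry_dbp) != self.bp_class:
            raise ValueError(
                f"bp_class {self.bp_class!r} inconsistent with entry BP "
                f"{self.entry_sbp:.0f}/{self.entry_dbp:.0f}"
            )


@dataclass
class ConditionBlock:
    condition: str
    n_observations: int
    duration_s: float


@dataclass
class SessionProtocol:
    """Ordered condition blocks with scheduled observation counts.

    Consecutive readings are separated by ``obs_spacing_s`` (>= 60 s, the
    venous-congestion delay); after each modulating activity the study takes
    three consecutive readings, which the default protocol mirrors.
    """

    blocks: list[ConditionBlock] = field(default_factory=list)
    obs_spacing_s: float = 75.0
    lead_in_s: float = 70.0  # settle time before the first reading of a block

    def __post_init__(self) -> None:
        if self.obs_spacing_s < 60:
            raise ValueError("observation spacing must be >= 60 s")
        for b in self.blocks:
            if b.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {b.condition!r}")
            needed = self.lead_in_s + b.n_observations * self.obs_spacing_s
            if b.duration_s < needed:
                raise ConfigError(
                    f"block {b.condition!r} duration {b.duration_s}s too short "
                    f"for {b.n_observations} observations (needs >= {needed}s)"
                )

    @property
    def total_duration(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    def schedule(self) -> list[tuple[str, float]]:
        """Scheduled (condition, observation time) pairs, session-relative."""
        out = []
        t0 = 0.0
        for b in self.blocks:
            for k in range(b.n_observations):
                out.append((b.condition, t0 + self.lead_in_s + (k + 1) * self.obs_spacing_s))
            t0 += b.duration_s
        return out


def default_protocol(obs_per_condition: int = 3,
                     obs_spacing_s: float = 75.0) -> SessionProtocol:
    """Static baseline, warm stimulus, cold pressor + walk, then rest."""
    lead_in = 70.0
    dur = lead_in + (obs_per_condition + 1) * obs_spacing_s
    blocks = [ConditionBlock(c, obs_per_condition, dur) for c in CONDITIONS]
    return SessionProtocol(blocks, obs_spacing_s=obs_spacing_s, lead_in_s=lead_in)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def stratified_counts(n_subjects: int, fractions) -> dict[str, int]:
    """Per-class subject counts: floor of each target fraction, with the
    rounding residual assigned to the largest-fraction class.

    Fractions may sum to slightly more or less than one (printed study
    percentages are rounded; 20/37/26/18 sums to 101%), so anything within
    2% of unity is accepted as-is.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or not math.isclose(fr.sum(), 1.0, abs_tol=0.02):
        raise ConfigError(f"class fractions must be >= 0 and sum to ~1, got {list(fr)}")
    counts = np.floor(fr * n_subjects).astype(int)
    counts[int(np.argmax(fr))] += n_subjects - counts.sum()
    return dict(zip(BP_CLASSES, (int(c) for c in counts)))


def generate_cohort(
    n_subjects: int,
    fractions=None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> list[SubjectProfile]:
    """Generate a stratified cohort with planted hemodynamics.

    Deterministic given ``(n_subjects, fractions, seed)``.  Sexes alternate
    through a seeded permutation so both are present whenever n >= 2.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects (one per class)")
    config = config or GeneratorConfig()
    fractions = fractions if fractions is not None else config.class_fractions
    counts = stratified_counts(n_subjects, fractions)
    rng = np.random.default_rng(seed)

    classes = [c for c, k in counts.items() for _ in range(k)]
    sexes = ["male" if i % 2 == 0 else "female" for i in range(n_subjects)]
    sexes = [sexes[i] for i in rng.permutation(n_subjects)]

    subjects = []
    for i, (bp_class, sex) in enumerate(zip(classes, sexes)):
        (slo, shi), (dlo, dhi) = _CLASS_BP_RANGES[bp_class]
        entry_sbp = rng.uniform(slo, shi)
        entry_dbp = rng.uniform(dlo, dhi)
        entry_dbp = min(entry_dbp, entry_sbp - 20)  # keep a realistic pulse pressure
        alo, ahi = _CLASS_AGE_RANGES[bp_class]
        age = int(rng.integers(alo, ahi + 1))
        height = float(np.clip(rng.normal(176 if sex == "male" else 163, 7), 145, 205))
        bmi = float(np.clip(rng.normal(27, 4), 18, 42))
        weight = round(bmi * (height / 100) ** 2, 1)
        subject = SubjectProfile(
            subject_id=f"S{i:03d}",
            age=age, sex=sex, height=round(height, 1), weight=weight,
            entry_sbp=entry_sbp, entry_dbp=entry_dbp, bp_class=bp_class,
            truth=None,
        )
        subject.truth = _draw_truth(subject, rng, config)
        subjects.append(subject)
    return subjects


def _draw_truth(subject: SubjectProfile, rng: np.random.Generator,
                config: GeneratorConfig) -> GroundTruthHemodynamics:
    c = config.coupling
    condition_bp = {}
    for cond in CONDITIONS:
        off_s, off_d = getattr(config, f"offset_{cond}")
        sbp = subject.entry_sbp + off_s + rng.normal(0, config.subject_sd[0])
        dbp = subject.entry_dbp + off_d + rng.normal(0, config.subject_sd[1])
        dbp = min(dbp, sbp - 15)
        condition_bp[cond] = (float(sbp), float(dbp))

    heart_rate = float(rng.uniform(58, 90))
    r_to_s1 = float(rng.uniform(0.030, 0.060))
    if c.enabled:
        r_to_s2 = float(coupled_r_to_s2(subject.entry_sbp, c))
    else:
        r_to_s2 = float(rng.uniform(0.26, 0.34))
    return GroundTruthHemodynamics(
        condition_bp=condition_bp,
        heart_rate=heart_rate,
        respiration_rate=float(rng.uniform(9, 20)),
        r_to_s1=r_to_s1,
        r_to_s2=r_to_s2,
        qrs_duration=float(rng.uniform(0.07, 0.11)),
        tidal_amplitude=float(rng.uniform(0.5, 2.0)),
        baseline_impedance=float(rng.uniform(25, 45)),
    )


def coupled_r_to_s2(sbp, coupling: CouplingConfig):
    """Planted monotone-decreasing affine map from SBP to the R->S2 delay.

    Clipped to [0.19, 0.40] s so extreme BP draws stay inside the
    physiological systolic interval (and the S2 search region).
    """
    raw = coupling.r_to_s2_anchor + coupling.r_to_s2_slope * (np.asarray(sbp) - 120.0)
    return np.clip(raw, 0.19, 0.40)


def coupled_s1s2_ratio(dbp: float, coupling: CouplingConfig) -> float:
    """Planted affine map from DBP to the S1/S2 RMS amplitude ratio."""
    return max(0.2, coupling.s1s2_ratio_anchor + coupling.s1s2_ratio_slope * (dbp - 80.0))


# --------------------------------------------------------------------------
# condition BP and observers
# --------------------------------------------------------------------------

def simulate_condition_bp(
    subject: SubjectProfile,
    condition: str,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> tuple[float, float]:
    """One observation's true (SBP, DBP) under a protocol condition.

    The subject-level condition response was drawn once at cohort generation
    (SD ``subject_sd``); this adds the observation-to-observation variability
    (SD ``observation_sd``) around it.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = config or GeneratorConfig()
    base_s, base_d = subject.truth.condition_bp[condition]
    sbp = base_s + rng.normal(0, config.observation_sd[0])
    dbp = base_d + rng.normal(0, config.observation_sd[1])
    dbp = min(dbp, sbp - 15)
    return float(sbp), float(dbp)


def round_to_grid(value, grid: float = 2.0):
    """Round to the nearest multiple of ``grid`` (ties to even multiples)."""
    return grid * np.round(np.asarray(value, dtype=float) / grid)


def simulate_observers(
    true_sbp: float,
    true_dbp: float,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> dict[str, float]:
    """Dual-observer readings plus the sequential wrist-cuff column.

    Each observer reads true + independent N(0, observer_noise_sd) noise,
    recorded to the nearest 2 mmHg; under the default 2-mmHg noise about 9%
    of pairs disagree by more than 4 mmHg, exercising the retake rule.  The
    wrist cuff carries a larger bias and noise so its MAD exceeds a decent
    model's.
    """
    if true_sbp <= 0 or true_dbp <= 0:
        raise ValueError("true pressures must be positive")
    config = config or GeneratorConfig()
    sd = config.observer_noise_sd
    out = {}
    for name, true in (("sbp", true_sbp), ("dbp", true_dbp)):
        out[f"obs1_{name}"] = float(round_to_grid(true + rng.normal(0, sd)))
        out[f"obs2_{name}"] = float(round_to_grid(true + rng.normal(0, sd)))
        out[f"cuff_{name}"] = float(
            round_to_grid(true + config.cuff_bias + rng.normal(0, config.cuff_noise_sd))
        )
    return out


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------

def _add_gaussian(x: np.ndarray, fs: float, center_s: float, sigma_s: float,
                  amp: float) -> None:
    """Add amp*exp(-(t-center)^2 / 2 sigma^2) onto x in place (local slice)."""
    half = 5.0 * sigma_s
    i0 = max(0, int((center_s - half) * fs))
    i1 = min(len(x), int((center_s + half) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    x[i0:i1] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def _add_tone_burst(x: np.ndarray, fs: float, center_s: float, sigma_s: float,
                    freq: float, amp: float) -> None:
    """Add a Gaussian-windowed cosine burst centred at ``center_s``."""
    half = 5.0 * sigma_s
    i0 = max(0, int((center_s - half) * fs))
    i1 = min(len(x), int((center_s + half) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    env = np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)
    x[i0:i1] += amp * env * np.cos(2 * np.pi * freq * (t - center_s))


#: Gaussian QRS: |g| exceeds 10% of the R amplitude over 2*sqrt(2 ln 10) sigma,
#: so planting sigma = qrs_duration / that factor makes the 10%-threshold
#: width measurement recover qrs_duration exactly.
_QRS_WIDTH_FACTOR = 2.0 * math.sqrt(2.0 * math.log(10.0))

S1_FREQ = 30.0  # Hz, low-frequency dominant
S2_FREQ = 70.0  # Hz
S1_SIGMA = 0.018  # s, burst envelope width
S2_SIGMA = 0.014
S2_AMP = 0.5  # S2 burst amplitude; S1 amplitude = ratio * S2_AMP


@dataclass
class SyntheticSession:
    """One synthesized session: waveforms, observer rows and hidden truth."""

    recording: MultichannelRecording
    observations: list[BPObservation]
    truth: pd.DataFrame  # per observation: condition, t, true SBP/DBP, features
    subject: SubjectProfile


def synthesize_recording(
    subject: SubjectProfile,
    protocol: SessionProtocol,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    max_duration_s: float = 7200.0,
) -> SyntheticSession:
    """Synthesize raw waveforms plus scheduled observer readings.

    True BP is piecewise constant between scheduled readings: every beat in
    the interval ending at reading *i* is generated from reading *i*'s true
    BP, so the analysis window preceding an observation carries exactly the
    physiology that observation measures.
    """
    config = config or GeneratorConfig()
    if protocol.total_duration > max_duration_s:
        raise ConfigError(
            f"protocol duration {protocol.total_duration}s exceeds "
            f"max_duration_s={max_duration_s}"
        )
    rng = np.random.default_rng(seed)
    truth = subject.truth
    duration = protocol.total_duration
    schedule = protocol.schedule()

    # per-observation true BP
    obs_times = np.array([t for _, t in schedule])
    obs_bp = np.array([
        simulate_condition_bp(subject, cond, rng, config)
        for cond, _ in schedule
    ])

    # beat times
    mean_rr = 60.0 / truth.heart_rate
    n_beats = int(duration / (mean_rr * (1 - 3 * config.hrv_rel_sd))) + 2
    rr = mean_rr * (1.0 + config.hrv_rel_sd * rng.standard_normal(n_beats))
    r_times = 0.4 + np.cumsum(rr)
    r_times = r_times[r_times < duration - 1.0]

    # per-beat BP: the next scheduled observation's true value
    idx = np.minimum(np.searchsorted(obs_times, r_times), len(obs_times) - 1)
    beat_sbp = obs_bp[idx, 0]
    beat_dbp = obs_bp[idx, 1]

    c = config.coupling
    if c.enabled:
        beat_s2 = coupled_r_to_s2(beat_sbp, c)
        beat_ratio = np.array([coupled_s1s2_ratio(d, c) for d in beat_dbp])
    else:
        beat_s2 = np.full_like(beat_sbp, truth.r_to_s2)
        beat_ratio = np.full_like(beat_dbp, 1.5)

    qrs_sigma = truth.qrs_duration / _QRS_WIDTH_FACTOR

    # --- ECG
    n_ecg = int(duration * config.fs_ecg)
    ecg = np.zeros(n_ecg)
    for r in r_times:
        _add_gaussian(ecg, config.fs_ecg, r - 0.16, 0.020, 0.12)  # P
        _add_gaussian(ecg, config.fs_ecg, r, qrs_sigma, 1.0)      # QRS
        _add_gaussian(ecg, config.fs_ecg, r + 0.30, 0.055, 0.25)  # T
    if config.ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0, config.ecg_noise_sd, n_ecg)
    ecg2 = 0.8 * ecg

    # --- PCG
    n_pcg = int(duration * config.fs_pcg)
    pcg = np.zeros(n_pcg)
    for r, s2t, ratio in zip(r_times, beat_s2, beat_ratio):
        _add_tone_burst(pcg, config.fs_pcg, r + truth.r_to_s1, S1_SIGMA,
                        S1_FREQ, ratio * S2_AMP)
        _add_tone_burst(pcg, config.fs_pcg, r + s2t, S2_SIGMA, S2_FREQ, S2_AMP)
    if config.pcg_noise_sd > 0:
        pcg = pcg + rng.normal(0, config.pcg_noise_sd, n_pcg)

    # --- impedance (respiration + small cardiac ripple)
    f_resp = truth.respiration_rate / 60.0
    t_imp = np.arange(int(duration * config.fs_imp)) / config.fs_imp
    resp = np.sin(2 * np.pi * f_resp * t_imp)
    ripple = 0.03 * truth.tidal_amplitude * np.sin(2 * np.pi * (truth.heart_rate / 60.0) * t_imp)
    imp1 = truth.baseline_impedance + truth.tidal_amplitude * resp + ripple
    imp2 = (0.9 * truth.baseline_impedance
            + 0.8 * truth.tidal_amplitude * np.sin(2 * np.pi * f_resp * t_imp + 0.6)
            + ripple)
    if config.imp_noise_sd > 0:
        imp1 = imp1 + rng.normal(0, config.imp_noise_sd, len(t_imp))
        imp2 = imp2 + rng.normal(0, config.imp_noise_sd, len(t_imp))

    # --- activity + movement artifacts corrupting all channels
    act = np.zeros(int(duration * config.fs_act))
    for t0, dur in config.movement_epochs:
        a0, a1 = int(t0 * config.fs_act), int((t0 + dur) * config.fs_act)
        act[a0:a1] = 2.0 + np.abs(rng.normal(0, 1.0, max(0, a1 - a0)))
        for arr, fs, scale in ((ecg, config.fs_ecg, 1.0), (pcg, config.fs_pcg, 0.5),
                               (imp1, config.fs_imp, 2.0), (imp2, config.fs_imp, 2.0)):
            j0, j1 = int(t0 * fs), int((t0 + dur) * fs)
            arr[j0:j1] += rng.normal(0, config.movement_amplitude * scale, max(0, j1 - j0))

    recording = MultichannelRecording(
        subject_id=subject.subject_id,
        channels={
            "ecg1": Channel(ecg, config.fs_ecg, "mV"),
            "ecg2": Channel(ecg2, config.fs_ecg, "mV"),
            "pcg": Channel(pcg, config.fs_pcg, "a.u."),
            "imp1": Channel(imp1, config.fs_imp, "ohm"),
            "imp2": Channel(imp2, config.fs_imp, "ohm"),
            "activity": Channel(act, config.fs_act, "g"),
        },
    )

    observations: list[BPObservation] = []
    truth_rows = []
    for k, ((cond, t_obs), (sbp, dbp)) in enumerate(zip(schedule, obs_bp)):
        readings = simulate_observers(sbp, dbp, rng, config)
        oid = f"{subject.subject_id}-{k:02d}"
        observations.append(BPObservation(
            observation_id=oid, subject_id=subject.subject_id,
            timestamp_s=float(t_obs), condition=cond, **readings,
        ))
        truth_rows.append({
            "observation_id": oid, "condition": cond, "timestamp_s": t_obs,
            "true_sbp": sbp, "true_dbp": dbp,
            "true_r_to_s1": truth.r_to_s1,
            "true_r_to_s2": float(coupled_r_to_s2(sbp, c)) if c.enabled else truth.r_to_s2,
            "true_ibi": mean_rr if config.hrv_rel_sd == 0 else np.nan,
            "true_resp_rate": truth.respiration_rate,
            "true_rtv1": 2.0 * truth.tidal_amplitude / truth.baseline_impedance,
            "true_qrs": truth.qrs_duration,
        })
    return SyntheticSession(recording, observations, pd.DataFrame(truth_rows), subject)


# --------------------------------------------------------------------------
# feature-level fast path
# --------------------------------------------------------------------------

#: measurement-noise SDs of the feature-level generator (per observation).
FEATURE_NOISE_SD = {
    "r_to_s1": 0.003,
    "r_to_s2": 0.003,
    "mean_interbeat_interval": 0.015,
    "s1s2_rms_ratio": 0.05,
    "s1_rms": 0.015,
    "s2_rms": 0.015,
    "respiration_rate": 0.5,
    "relative_tidal_volume": 0.004,
    "mean_impedance": 0.3,
    "qrs_duration": 0.002,
    "band_rms": 0.02,
}
#: subject-level baseline offset SD for the S2 timing (between-subject
#: variation the coupling does not explain).
R_TO_S2_SUBJECT_SD = 0.005


def simulate_feature_dataset(
    n_subjects: int,
    obs_per_subject: int,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Draw the per-observation feature matrix directly from planted truth.

    Bypasses waveform synthesis/extraction: each signal feature is its
    planted ground-truth value (including the configured BP coupling) plus
    subject-level and observation-level noise, with observer-reconciled
    reference targets.  Rows carry subject_id, condition, the reference
    sbp_ref/dbp_ref, true BP, and wrist-cuff columns.  Discordant observer
    pairs (> 4 mmHg) are retaken as in the study protocol, so the row count
    is exactly ``n_subjects * obs_per_subject``.
    """
    config = config or GeneratorConfig()
    cohort = generate_cohort(n_subjects, config.class_fractions, seed, config)
    rng = np.random.default_rng(seed + 1)
    c = config.coupling
    nsd = FEATURE_NOISE_SD

    conditions = [CONDITIONS[i % 4] for i in range(obs_per_subject)]
    rows = []
    for subject in cohort:
        tr = subject.truth
        s2_base = rng.normal(0, R_TO_S2_SUBJECT_SD)
        ratio_base = rng.normal(0, 0.08)
        for k, cond in enumerate(conditions):
            sbp, dbp = simulate_condition_bp(subject, cond, rng, config)
            readings = _reconciled_readings(sbp, dbp, rng, config)

            if c.enabled:
                r_to_s2 = coupled_r_to_s2(sbp, c) + s2_base
                ratio = coupled_s1s2_ratio(dbp, c) + ratio_base
                rtv1 = (2 * tr.tidal_amplitude / tr.baseline_impedance
                        + c.tidal_slope * (sbp - 120.0))
            else:
                r_to_s2 = tr.r_to_s2 + s2_base
                ratio = 1.5 + ratio_base
                rtv1 = 2 * tr.tidal_amplitude / tr.baseline_impedance
            rtv2 = rtv1 * 0.8 / 0.9
            s2_rms = S2_AMP + rng.normal(0, nsd["s2_rms"])
            s1_rms = ratio * S2_AMP + rng.normal(0, nsd["s1_rms"])
            row = {
                "observation_id": f"{subject.subject_id}-{k:02d}",
                "subject_id": subject.subject_id,
                "condition": cond,
                "sbp_ref": readings["sbp_ref"],
                "dbp_ref": readings["dbp_ref"],
                "true_sbp": sbp,
                "true_dbp": dbp,
                "cuff_sbp": readings["cuff_sbp"],
                "cuff_dbp": readings["cuff_dbp"],
                "respiration_rate_1": tr.respiration_rate + rng.normal(0, nsd["respiration_rate"]),
                "respiration_rate_2": tr.respiration_rate + rng.normal(0, nsd["respiration_rate"]),
                "relative_tidal_volume_1": max(0.0, rtv1 + rng.normal(0, nsd["relative_tidal_volume"])),
                "relative_tidal_volume_2": max(0.0, rtv2 + rng.normal(0, nsd["relative_tidal_volume"])),
                "mean_impedance": tr.baseline_impedance + rng.normal(0, nsd["mean_impedance"]),
                "r_to_s1": tr.r_to_s1 + rng.normal(0, nsd["r_to_s1"]),
                "r_to_s2": r_to_s2 + rng.normal(0, nsd["r_to_s2"]),
                "mean_interbeat_interval": 60.0 / tr.heart_rate + rng.normal(0, nsd["mean_interbeat_interval"]),
                "s1s2_rms_ratio": s1_rms / s2_rms,
                "s1_rms": s1_rms,
                "s2_rms": s2_rms,
                "s_low": 0.4 * s1_rms + np.abs(rng.normal(0, nsd["band_rms"])),
                "s_mid": 0.4 * s2_rms + np.abs(rng.normal(0, nsd["band_rms"])),
                "s_high": np.abs(rng.normal(0, nsd["band_rms"])),
                "s1_low": 0.35 * s1_rms + np.abs(rng.normal(0, nsd["band_rms"])),
                "qrs_duration": tr.qrs_duration + rng.normal(0, nsd["qrs_duration"]),
                "age": subject.age,
                "sex_male": 1.0 if subject.sex == "male" else 0.0,
                "height": subject.height,
                "weight": subject.weight,
            }
            rows.append(row)
    return pd.DataFrame(rows)


def _reconciled_readings(sbp: float, dbp: float, rng: np.random.Generator,
                         config: GeneratorConfig, max_retakes: int = 20) -> dict:
    """Observer pair with protocol retakes until both components reconcile."""
    from .reference_bp import reconcile_observers  # local to avoid warn noise

    for _ in range(max_retakes):
        r = simulate_observers(sbp, dbp, rng, config)
        s = reconcile_observers(r["obs1_sbp"], r["obs2_sbp"])
        d = reconcile_observers(r["obs1_dbp"], r["obs2_dbp"])
        if s is not None and d is not None:
            return {"sbp_ref": s, "dbp_ref": d,
                    "cuff_sbp": r["cuff_sbp"], "cuff_dbp": r["cuff_dbp"]}
    # pathological noise settings only: fall back to the last readings' means
    return {"sbp_ref": (r["obs1_sbp"] + r["obs2_sbp"]) / 2,
            "dbp_ref": (r["obs1_dbp"] + r["obs2_dbp"]) / 2,
            "cuff_sbp": r["cuff_sbp"], "cuff_dbp": r["cuff_dbp"]}
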