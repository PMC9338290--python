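"""Pipeline configuration: nested dataclasses, YAML (de)serialisation, hashing.

Every stage of the pipeline draws its tunables from :class:`PipelineConfig`;
every random operation takes an explicit seed.  The config hash (sha256 of the
canonical JSON form) is recorded in all stage manifests so outputs can be
traced back to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class CouplingConfig:
    """How the planted hemodynamics couple waveform features to true BP.

    The couplings are the generator's ground truth: they exist so that
    parameter-recovery and model-superiority tests have a known answer.  With
    ``enabled=False`` the signal features are statistically independent of BP
    (null mode).
    """

    enabled: bool = True
    #: d(r_to_s2)/d(SBP) in s/mmHg; negative (higher SBP -> earlier S2).
    #: The magnitude is set so the planted effect spans ~100 ms over the
    #: cohort's SBP range — large against the generator's measurement noise,
    #: making the planted answer reliably recoverable at the default study
    #: size (which is the coupling's entire purpose).
    r_to_s2_slope: float = -0.0012
    #: r_to_s2 at the 120 mmHg SBP anchor, seconds.
    r_to_s2_anchor: float = 0.300
    #: d(S1/S2 RMS ratio)/d(DBP) per mmHg.
    s1s2_ratio_slope: float = 0.02
    #: S1/S2 RMS ratio at the 80 mmHg DBP anchor.
    s1s2_ratio_anchor: float = 1.5
    #: weak coupling of relative tidal volume to SBP, per mmHg.
    tidal_slope: float = -0.0003


@dataclass
class GeneratorConfig:
    """Synthetic-study generator parameters (cohort, protocol, waveforms)."""

    # channel sampling rates, Hz
    fs_ecg: float = 500.0
    fs_pcg: float = 500.0
    fs_imp: float = 50.0
    fs_act: float = 25.0
    # cohort stratification target fractions: normal/prehtn/stage1/stage2
    class_fractions: tuple[float, float, float, float] = (0.20, 0.37, 0.26, 0.18)
    # condition mean offsets to (SBP, DBP), mmHg
    offset_static: tuple[float, float] = (0.0, 0.0)
    offset_warm_rest: tuple[float, float] = (-9.0, -5.0)
    offset_cold_walk: tuple[float, float] = (12.0, 8.0)
    offset_rest: tuple[float, float] = (-3.0, -2.0)
    # subject-level condition-reactivity SD and observation-level SD, mmHg
    subject_sd: tuple[float, float] = (3.0, 2.0)
    observation_sd: tuple[float, float] = (4.0, 3.0)
    # observer model
    observer_noise_sd: float = 2.0
    cuff_bias: float = 3.0
    cuff_noise_sd: float = 7.0
    # waveform noise (0 => noise-free synthesis)
    ecg_noise_sd: float = 0.0
    pcg_noise_sd: float = 0.0
    imp_noise_sd: float = 0.0
    hrv_rel_sd: float = 0.0
    # movement artifacts: list of (start_s, duration_s) epochs
    movement_epochs: tuple[tuple[float, float], ...] = ()
    movement_amplitude: float = 5.0
    coupling: CouplingConfig = field(default_factory=CouplingConfig)


@dataclass
class QualityConfig:
    """Signal-quality criteria (per-second screening)."""

    saturation_run: int = 50  # consecutive samples pinned at the channel rail
    variance_floor: float = 1e-10  # per-second variance below this = flatline
    movement_threshold: float = 1.0  # activity-channel absolute threshold
    rr_min: float = 0.3  # plausible RR interval bounds, s
    rr_max: float = 2.0


@dataclass
class WindowConfig:
    """Window association: 60-s analysis window in a 300-s lookback."""

    lookback_s: float = 300.0
    window_s: float = 60.0
    #: "preceding" = latest acceptable window before the observation;
    #: "centered" = acceptable window closest to being centred on it.
    mode: str = "preceding"


@dataclass
class FeatureConfig:
    """Feature-extraction tunables."""

    # heart-sound spectral bands, Hz
    band_low: tuple[float, float] = (20.0, 50.0)
    band_mid: tuple[float, float] = (50.0, 100.0)
    band_high: tuple[float, float] = (100.0, 240.0)  # upper edge < Nyquist at 500 Hz
    s_window_ms: float = 40.0  # half-window around S1/S2 for RMS
    s1_region: tuple[float, float] = (0.0, 0.18)  # fractions of RR
    s2_region: tuple[float, float] = (0.18, 0.60)
    resp_band_hz: tuple[float, float] = (0.07, 1.0)
    qrs_threshold: float = 0.10  # fraction of R amplitude
    min_beats: int = 5
    beat_corr_min: float = 0.5  # ensemble outlier-beat exclusion
    #: drop an observation when more than this fraction of signal features is
    #: missing; 0.45 keeps a window with all heart-sound features missing
    #: (6/16) usable, since the ECG and impedance features are intact.
    max_missing_fraction: float = 0.45


@dataclass
class ModelConfig:
    """Splitting, selection and ensemble training parameters."""

    train_fraction: float = 0.8
    selection_threshold: float = 0.02
    selection_n_trees: int = 200
    split_level: str = "observation"  # or "subject"
    n_rf: int = 100
    n_gbr: int = 100
    n_bag: int = 50


@dataclass
class EvalConfig:
    n_bootstrap_rmse: int = 10_000
    n_bootstrap_mad: int = 1_000


@dataclass
class PipelineConfig:
    """Top-level configuration for an end-to-end run."""

    seed: int = 0
    n_subjects: int = 40
    obs_per_subject: int = 8
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


class ConfigError(ValueError):
    """Raised on schema violations; the message names the offending field."""


def _build(cls, data):
    """Recursively build a dataclass from a nested dict, validating keys."""
    if not dataclasses.is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown field(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        target = _DATACLASS_FIELDS.get((cls.__name__, name))
        if target is not None:
            kwargs[name] = _build(target, value)
        elif isinstance(value, list):
            kwargs[name] = _tuplify(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


# nested-dataclass fields that need recursive construction from YAML
_DATACLASS_FIELDS = {
    ("GeneratorConfig", "coupling"): CouplingConfig,
    ("PipelineConfig", "generator"): GeneratorConfig,
    ("PipelineConfig", "quality"): QualityConfig,
    ("PipelineConfig", "window"): WindowConfig,
    ("PipelineConfig", "features"): FeatureConfig,
    ("PipelineConfig", "model"): ModelConfig,
    ("PipelineConfig", "evaluation"): EvalConfig,
}
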