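"""Signal-quality screening and window association.

Movement-corrupted or otherwise unusable data is excluded, never repaired:
each recording gets a per-second quality mask, and each cuff observation is
paired with the latest fully-acceptable 60-s window inside the 300-s lookback
preceding its timestamp.  Observations with no acceptable window are
rejected with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import QualityConfig, WindowConfig
from .signal_io import BPObservation, Channel, MultichannelRecording

log = logging.getLogger(__name__)

#: channels whose quality feeds the composite flag
REQUIRED_CHANNELS = ("ecg1", "ecg2", "pcg", "imp1", "imp2")
#: channels screened for flatline; the PCG is legitimately near-silent
#: between heart sounds and the activity channel is near-zero at rest,
#: so the flatline criterion applies to the ECG and impedance channels.
FLATLINE_CHANNELS = ("ecg1", "ecg2", "imp1", "imp2")


@dataclass
class QualityMask:
    """Per-second acceptability flags (True = acceptable)."""

    per_channel: dict[str, np.ndarray]
    composite: np.ndarray  # acceptable only if every required channel is

    @property
    def n_seconds(self) -> int:
        return len(self.composite)


@dataclass
class AnalysisWindow:
    """The 60-s segment of acceptable data paired with one observation."""

    observation: BPObservation
    window_start: float  # s, half-open [start, end)
    window_end: float
    channels: dict[str, Channel]

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("window_end must exceed window_start")


@dataclass
class WindowRejection:
    observation_id: str
    reason: str


def _has_saturation_run(x: np.ndarray, rail: float, run: int) -> bool:
    """Run of >= ``run`` consecutive *constant* samples at the amplitude rail.

    ADC clipping pins the output to a constant extreme value; a physiological
    signal near its peak still varies sample to sample.  ``rail`` is 99% of
    the channel's peak magnitude (an all-zero channel has rail 0 and is one
    long saturated run).
    """
    if len(x) < run:
        return False
    const = np.concatenate(([True], np.diff(x) == 0))
    sat = const & (np.abs(x) >= rail)
    if sat.sum() < run:
        return False
    changes = np.diff(np.concatenate(([0], sat.view(np.int8), [0])))
    starts = np.flatnonzero(changes == 1)
    ends = np.flatnonzero(changes == -1)
    return bool(len(starts) and (ends - starts).max() >= run)


def assess_quality(rec: MultichannelRecording,
                   params: QualityConfig | None = None) -> QualityMask:
    """Screen a recording second by second.

    A second of a channel is unacceptable if it shows amplitude saturation
    (>= ``saturation_run`` consecutive samples pinned near the channel's
    peak magnitude, i.e. ADC clipping), a flatline (variance below the
    floor, ECG/impedance channels), movement (activity channel above
    threshold), or an implausible local RR interval (outside
    [rr_min, rr_max] s) on the primary ECG.
    """
    params = params or QualityConfig()
    n_seconds = int(rec.duration)
    if n_seconds < 1:
        raise ValueError("recording shorter than 1 s")

    per_channel: dict[str, np.ndarray] = {}
    for name, ch in rec.channels.items():
        good = np.ones(n_seconds, dtype=bool)
        spp = int(ch.fs)  # samples per second
        rail = 0.99 * float(np.abs(ch.samples).max())
        for s in range(n_seconds):
            seg = ch.samples[s * spp:(s + 1) * spp]
            if name == "activity":
                if np.abs(seg).max(initial=0.0) > params.movement_threshold:
                    good[s] = False
                continue
            if _has_saturation_run(seg, rail, params.saturation_run):
                good[s] = False
            elif name in FLATLINE_CHANNELS and seg.var() < params.variance_floor:
                good[s] = False
        per_channel[name] = good

    # beat-interval consistency on the primary ECG
    if "ecg1" in rec.channels:
        _flag_rr_inconsistency(rec.channels["ecg1"], per_channel["ecg1"], params)

    composite = np.ones(n_seconds, dtype=bool)
    for name in REQUIRED_CHANNELS:
        if name in per_channel:
            composite &= per_channel[name]
    if "activity" in per_channel:
        composite &= per_channel["activity"]
    return QualityMask(per_channel, composite)


def _flag_rr_inconsistency(ecg: Channel, good: np.ndarray,
                           params: QualityConfig) -> None:
    """Flag seconds spanned by physiologically impossible RR intervals."""
    from .feature_extraction import detect_r_peaks_raw  # no module cycle

    n_seconds = len(good)
    try:
        r_times = detect_r_peaks_raw(ecg.samples, ecg.fs)
    except ValueError:
        return  # undetectable beats are caught by the other criteria
    if len(r_times) < 2:
        return
    rr = np.diff(r_times)
    for t0, dt in zip(r_times[:-1], rr):
        if not (params.rr_min <= dt <= params.rr_max):
            s0 = max(0, int(t0))
            s1 = min(n_seconds, int(t0 + dt) + 1)
            good[s0:s1] = False


def associate_window(
    mask: QualityMask,
    rec: MultichannelRecording,
    obs: BPObservation,
    config: WindowConfig | None = None,
) -> AnalysisWindow | WindowRejection:
    """Pair an observation with an acceptable analysis window.

    In the default ``"preceding"`` mode, candidate windows are anchored at
    the observation timestamp and stepped back one second at a time through
    the lookback; the latest fully-acceptable one wins.  In ``"centered"``
    mode the acceptable window whose centre is closest to the timestamp wins
    (later window on ties).  A lookback extending before the start of the
    recording is truncated to the available data.
    """
    config = config or WindowConfig()
    t_obs = obs.timestamp_s
    w = config.window_s
    earliest = max(0.0, t_obs - config.lookback_s)
    if t_obs - config.lookback_s < 0:
        log.info("observation %s: lookback truncated to [0, %.0f)",
                 obs.observation_id, t_obs)

    if config.mode == "preceding":
        latest_start = t_obs - w
        candidates = _step_back_starts(latest_start, earliest)
    elif config.mode == "centered":
        starts = _step_back_starts(min(t_obs - w / 2, mask.n_seconds - w), earliest)
        candidates = sorted(starts, key=lambda s: (abs(s + w / 2 - t_obs), -s))
    else:
        raise ValueError(f"unknown window mode {config.mode!r}")

    for start in candidates:
        if _window_acceptable(mask, start, start + w):
            channels = {
                name: ch.seconds_slice(start, start + w)
                for name, ch in rec.channels.items()
            }
            return AnalysisWindow(obs, start, start + w, channels)
    return WindowRejection(obs.observation_id, "no_acceptable_window")


def _step_back_starts(latest: float, earliest: float) -> list[float]:
    starts = []
    s = latest
    while s >= earliest - 1e-9:
        starts.append(s)
        s -= 1.0
    return starts


def _window_acceptable(mask: QualityMask, start: float, end: float) -> bool:
    """All mask-seconds overlapping [start, end) must be acceptable."""
    if start < -1e-9:
        return False
    s0 = int(np.floor(start + 1e-9))
    s1 = int(np.ceil(end - 1e-9))
    if s1 > mask.n_seconds:
        return False
    return bool(mask.composite[s0:s1].all())
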