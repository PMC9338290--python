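"""File formats and in-memory containers for recordings and observations.

A recording is stored as a directory: one plain-text CSV per channel plus a
``header.json`` carrying sampling rates, units and start time (a WFDB-style
record layout in portable text form).  Cuff observations, reconciled
references and feature matrices are CSV with locale-independent numerics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical channel names: two ECG leads, phonocardiogram, two thoracic
#: impedance channels (thoracic and abdominal belts), and the accelerometer
#: activity channel.
CHANNEL_NAMES = ("ecg1", "ecg2", "pcg", "imp1", "imp2", "activity")

PRESSURE_RANGE = (40.0, 300.0)

OBSERVATION_COLUMNS = [
    "observation_id", "subject_id", "timestamp_s", "condition",
    "obs1_sbp", "obs1_dbp", "obs2_sbp", "obs2_dbp", "cuff_sbp", "cuff_dbp",
]


class FormatError(ValueError):
    """Malformed file; the message names the offending field or channel."""


@dataclass
class Channel:
    samples: np.ndarray
    fs: float
    units: str = ""

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def seconds_slice(self, start: float, end: float) -> "Channel":
        """Return the [start, end) time slice as a new Channel."""
        i0 = int(round(start * self.fs))
        i1 = int(round(end * self.fs))
        return Channel(self.samples[i0:i1], self.fs, self.units)


@dataclass
class MultichannelRecording:
    """Time-aligned raw signal channels for one session of one subject."""

    subject_id: str
    channels: dict[str, Channel]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if name not in CHANNEL_NAMES:
                raise FormatError(f"unknown channel name: {name!r}")
            if ch.fs <= 0:
                raise FormatError(f"fs must be positive for channel {name!r}")
            if len(ch.samples) == 0:
                raise FormatError(f"empty samples for channel {name!r}")

    @property
    def duration(self) -> float:
        """Common duration, s (shortest channel governs)."""
        return min(ch.duration for ch in self.channels.values())


@dataclass
class BPObservation:
    """One time-stamped dual-observer cuff reading (plus optional wrist cuff).

    Timestamps are stored at seconds resolution from session start; the
    study protocol records them to the nearest minute, available as
    :attr:`timestamp_min`.
    """

    observation_id: str
    subject_id: str
    timestamp_s: float
    condition: str
    obs1_sbp: float
    obs1_dbp: float
    obs2_sbp: float
    obs2_dbp: float
    cuff_sbp: float | None = None
    cuff_dbp: float | None = None

    @property
    def timestamp_min(self) -> int:
        return int(self.timestamp_s // 60)


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as a directory of per-channel CSVs + JSON header."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "subject_id": rec.subject_id,
        "start_time": rec.start_time,
        "channels": {
            name: {"fs": ch.fs, "units": ch.units, "n_samples": len(ch.samples)}
            for name, ch in rec.channels.items()
        },
    }
    (path / "header.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    for name, ch in rec.channels.items():
        np.savetxt(path / f"{name}.csv", ch.samples, fmt="%.8g")
    return path


def read_recording(path: str | Path) -> MultichannelRecording:
    path = Path(path)
    header_path = path / "header.json"
    if not header_path.exists():
        raise FormatError(f"missing header.json in {path}")
    header = json.loads(header_path.read_text())
    channels: dict[str, Channel] = {}
    for name, meta in header["channels"].items():
        fs = float(meta["fs"])
        if fs <= 0:
            raise FormatError(f"fs must be positive for channel {name!r}")
        data_path = path / f"{name}.csv"
        if not data_path.exists():
            raise FormatError(f"missing data file for channel {name!r}")
        samples = np.loadtxt(data_path, dtype=float, ndmin=1)
        if len(samples) != int(meta["n_samples"]):
            raise FormatError(
                f"length mismatch for channel {name!r}: header says "
                f"{meta['n_samples']}, file has {len(samples)}"
            )
        channels[name] = Channel(samples, fs, meta.get("units", ""))
    return MultichannelRecording(
        subject_id=header["subject_id"],
        channels=channels,
        start_time=float(header.get("start_time", 0.0)),
    )


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------

def write_observations(observations: list[BPObservation], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for o in observations:
        rows.append({c: getattr(o, c) for c in OBSERVATION_COLUMNS})
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)
    return path


def read_observations(path: str | Path) -> list[BPObservation]:
    """Parse an observations CSV.

    Rows with any pressure outside [40, 300] mmHg are rejected (logged with
    their row number); odd-mmHg readings violate the 2-mmHg recording grid
    and are warned about but retained, since real transcription may deviate
    from the grid.  Row order is preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns and not c.startswith("cuff")]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    observations: list[BPObservation] = []
    pressure_cols = ["obs1_sbp", "obs1_dbp", "obs2_sbp", "obs2_dbp"]
    lo, hi = PRESSURE_RANGE
    for i, row in df.iterrows():
        vals = [float(row[c]) for c in pressure_cols]
        if any(not (lo <= v <= hi) for v in vals):
            log.warning("row %d rejected: pressure outside [%g, %g] mmHg", i, lo, hi)
            continue
        if any(v % 2 != 0 for v in vals):
            warnings.warn(f"row {i}: reading off the 2-mmHg grid", stacklevel=2)
        observations.append(
            BPObservation(
                observation_id=str(row["observation_id"]),
                subject_id=str(row["subject_id"]),
                timestamp_s=float(row["timestamp_s"]),
                condition=str(row["condition"]),
                obs1_sbp=vals[0], obs1_dbp=vals[1],
                obs2_sbp=vals[2], obs2_dbp=vals[3],
                cuff_sbp=_opt(row.get("cuff_sbp")),
                cuff_dbp=_opt(row.get("cuff_dbp")),
            )
        )
    return observations


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


# --------------------------------------------------------------------------
# feature matrices
# --------------------------------------------------------------------------

def write_feature_matrix(df: pd.DataFrame, path: str | Path,
                         metadata: dict | None = None) -> Path:
    """Write the feature matrix CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, indent=1, sort_keys=True))
    return path


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta
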