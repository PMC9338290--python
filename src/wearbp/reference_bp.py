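"""Reference blood-pressure rules.

Implements the study-style handling of manual sphygmomanometer readings:

* dual-observer reconciliation — two trained observers read the same cuff via
  a Y-connector; readings within 4 mmHg are averaged, otherwise the
  measurement must be retaken;
* entry BP — the mean of three seated readings, used to classify subjects;
* JNC-7 blood-pressure classification;
* pairing of device/model estimates with reference values, either
  simultaneous (same-time reconciled reference) or the adjacent-mean rule of
  ISO 81060-2:2019 used for sequential devices such as a wrist cuff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np

BP_CLASSES = ("normal", "prehypertension", "stage1", "stage2")


@dataclass(frozen=True)
class ReferenceBP:
    """A reconciled reference value, or a rejection with reason."""

    observation_id: str
    sbp_ref: float | None
    dbp_ref: float | None
    status: str  # "ok" or "rejected"
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class EvaluationPair:
    """One (device estimate p_i, reference y_i) pair entering the metrics."""

    p: float
    y: float
    condition: str = ""
    split: str = ""
    observation_id: str = ""


def reconcile_observers(o1: float, o2: float) -> float | None:
    """Reconcile two simultaneous observer readings of one cuff measurement.

    Returns the mean when the observers agree to within 4 mmHg, otherwise
    ``None`` (the protocol requires a retake).  The mean of two even-grid
    readings may be odd; it is deliberately kept unrounded — the 2-mmHg grid
    applies to raw observer readings only.
    """
    for v in (o1, o2):
        if v % 2 != 0:
            warnings.warn(
                f"observer reading {v} is off the 2-mmHg grid", stacklevel=2
            )
    if abs(o1 - o2) <= 4:
        return (o1 + o2) / 2.0
    return None


def entry_bp(readings: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Entry BP: arithmetic mean of exactly three seated (SBP, DBP) readings."""
    if len(readings) != 3:
        raise ValueError(f"entry BP requires exactly 3 readings, got {len(readings)}")
    arr = np.asarray(readings, dtype=float)
    sbp, dbp = arr.mean(axis=0)
    return float(sbp), float(dbp)


def classify_jnc7(sbp: float, dbp: float) -> str:
    """JNC-7 class of a BP reading.

    Normal requires *both* SBP < 120 and DBP < 80; the hypertensive classes
    use or-logic and the highest class whose criterion is met wins, so the
    overlapping boundaries (SBP 160, DBP 100 appear in both the stage-1 range
    and the stage-2 threshold) resolve to stage 2.
    """
    if sbp >= 160 or dbp >= 100:
        return "stage2"
    if sbp >= 140 or dbp >= 90:
        return "stage1"
    if sbp >= 120 or dbp >= 80:
        return "prehypertension"
    return "normal"


def reconcile_observation(
    observation_id: str,
    obs1_sbp: float,
    obs1_dbp: float,
    obs2_sbp: float,
    obs2_dbp: float,
) -> ReferenceBP:
    """Reconcile both components of a dual-observer reading.

    The reference exists only when *both* the SBP pair and the DBP pair
    reconcile; otherwise the whole observation is rejected for retake.
    """
    sbp = reconcile_observers(obs1_sbp, obs2_sbp)
    dbp = reconcile_observers(obs1_dbp, obs2_dbp)
    if sbp is None or dbp is None:
        return ReferenceBP(observation_id, None, None, "rejected", "retake")
    return ReferenceBP(observation_id, sbp, dbp, "ok")


def make_pairs(
    device: Iterable[tuple[str, float, float]],
    references: Iterable[tuple[str, float, float]],
    mode: str = "simultaneous",
    conditions: dict[str, str] | None = None,
) -> list[EvaluationPair]:
    """Pair device/model readings with references.

    Parameters
    ----------
    device
        Iterable of ``(observation_id, timestamp_s, value)`` device readings.
    references
        Iterable of ``(observation_id, timestamp_s, value)`` accepted
        reference readings.
    mode
        ``"simultaneous"`` — y_i is the reference with the same observation
        id (the wearable records through the cuff measurement, so the pairing
        is exact).  ``"adjacent_mean"`` — y_i is the mean of the two
        references bracketing the device reading in time (sequential devices,
        per ISO 81060-2:2019); device readings without both brackets are
        dropped.
    conditions
        Optional observation-id -> condition-label map copied onto pairs.
    """
    conditions = conditions or {}
    refs = list(references)
    pairs: list[EvaluationPair] = []
    if mode == "simultaneous":
        ref_by_id = {r[0]: r[2] for r in refs}
        for oid, _t, p in device:
            if oid in ref_by_id:
                pairs.append(
                    EvaluationPair(
                        p=float(p), y=float(ref_by_id[oid]),
                        condition=conditions.get(oid, ""), observation_id=oid,
                    )
                )
    elif mode == "adjacent_mean":
        refs_sorted = sorted(refs, key=lambda r: r[1])
        ref_times = np.array([r[1] for r in refs_sorted], dtype=float)
        for oid, t, p in device:
            after = int(np.searchsorted(ref_times, t, side="left"))
            before = after - 1
            # a reference at exactly t cannot bracket a sequential reading
            if before < 0 or after >= len(refs_sorted) or ref_times[after] == t:
                continue
            y = (refs_sorted[before][2] + refs_sorted[after][2]) / 2.0
            pairs.append(
                EvaluationPair(
                    p=float(p), y=float(y),
                    condition=conditions.get(oid, ""), observation_id=oid,
                )
            )
    else:
        raise ValueError(f"unknown pairing mode: {mode!r}")
    return pairs
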