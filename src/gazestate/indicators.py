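"""Per-trial eye-movement indicators and outlier rejection.

Event lists are reduced to the indicator set used throughout the analysis:
Average / Median / SD Saccade Amplitude (deg), Average Blink Duration (ms),
Sac Avg Velocity and Sac Peak Velocity (deg/s, means of the per-saccade
average and peak velocities).  Indicators are computed per eye first and
then merged binocularly (arithmetic mean of the two eyes where both are
defined).  Indicators with no contributing events are NaN and excluded
listwise downstream.

Outliers are removed with the union of the box-plot rule
(outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]) and the 3-sigma rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EYES, GazeEvent, SampleStream
from .geometry import DEFAULT_GEOMETRY, DisplayGeometry
from .synth import TrialMeta

#: canonical per-trial indicator columns
INDICATOR_NAMES = (
    "avg_saccade_amplitude",
    "median_saccade_amplitude",
    "sd_saccade_amplitude",
    "avg_blink_duration",
    "sac_avg_velocity",
    "sac_peak_velocity",
)

#: display names used in table-style reports
DISPLAY_NAMES = {
    "avg_saccade_amplitude": "Average Saccade Amplitude",
    "median_saccade_amplitude": "Median Saccade Amplitude",
    "sd_saccade_amplitude": "SD Saccade Amplitude",
    "avg_blink_duration": "Average Blink Duration",
    "sac_avg_velocity": "Sac Avg Velocity",
    "sac_peak_velocity": "Sac Peak Velocity",
}


@dataclass
class IndicatorVector:
    avg_saccade_amplitude: float = np.nan
    median_saccade_amplitude: float = np.nan
    sd_saccade_amplitude: float = np.nan
    avg_blink_duration: float = np.nan
    sac_avg_velocity: float = np.nan
    sac_peak_velocity: float = np.nan
    n_saccades: int = 0
    n_blinks: int = 0
    channels: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in INDICATOR_NAMES}
        d["n_saccades"] = self.n_saccades
        d["n_blinks"] = self.n_blinks
        d.update(self.channels)
        return d


@dataclass
class TrialRecord:
    meta: TrialMeta
    per_eye: dict[str, IndicatorVector]
    binocular: IndicatorVector

    def to_row(self) -> dict:
        row = {"subject_id": self.meta.subject_id,
               "paradigm": self.meta.paradigm,
               "group": self.meta.group,
               "repetition": self.meta.repetition,
               "state": self.meta.state}
        row.update(self.binocular.as_dict())
        for eye in EYES:
            for name in INDICATOR_NAMES:
                row[f"{eye}_{name}"] = getattr(self.per_eye[eye], name)
        return row


def _eye_indicators(events: Sequence[GazeEvent], stream: SampleStream,
                    eye: str, geometry: DisplayGeometry) -> IndicatorVector:
    saccades = [e for e in events if e.kind == "saccade"]
    blinks = [e for e in events if e.kind == "blink"]
    vec = IndicatorVector(n_saccades=len(saccades), n_blinks=len(blinks))
    if saccades:
        amps = np.array([e.amplitude_deg for e in saccades], dtype=float)
        vec.avg_saccade_amplitude = float(amps.mean())
        vec.median_saccade_amplitude = float(np.median(amps))
        # sample SD (n-1): per-trial saccade counts are small
        vec.sd_saccade_amplitude = float(amps.std(ddof=1)) \
            if len(amps) >= 2 else np.nan
        vec.sac_avg_velocity = float(np.mean([e.avg_velocity
                                              for e in saccades]))
        vec.sac_peak_velocity = float(np.mean([e.peak_velocity
                                               for e in saccades]))
    if blinks:
        vec.avg_blink_duration = float(np.mean([e.duration_ms
                                                for e in blinks]))
    gaze = stream.gaze_deg(eye, geometry)
    pupil = stream.pupil(eye)
    valid = np.all(np.isfinite(gaze), axis=1)
    pvalid = np.isfinite(pupil) & (pupil > 0)
    if valid.any():
        vec.channels["gaze_x_mean"] = float(gaze[valid, 0].mean())
        vec.channels["gaze_x_sd"] = float(gaze[valid, 0].std(ddof=1))
        vec.channels["gaze_y_mean"] = float(gaze[valid, 1].mean())
        vec.channels["gaze_y_sd"] = float(gaze[valid, 1].std(ddof=1))
    if pvalid.any():
        vec.channels["pupil_mean"] = float(pupil[pvalid].mean())
        vec.channels["pupil_sd"] = float(pupil[pvalid].std(ddof=1))
    return vec


def _binocular_merge(left: IndicatorVector,
                     right: IndicatorVector) -> IndicatorVector:
    bino = IndicatorVector(n_saccades=left.n_saccades + right.n_saccades,
                           n_blinks=left.n_blinks + right.n_blinks)
    for name in INDICATOR_NAMES:
        a, b = getattr(left, name), getattr(right, name)
        if np.isfinite(a) and np.isfinite(b):
            setattr(bino, name, (a + b) / 2.0)
        elif np.isfinite(a):
            setattr(bino, name, a)
        elif np.isfinite(b):
            setattr(bino, name, b)
    keys = set(left.channels) & set(right.channels)
    bino.channels = {k: (left.channels[k] + right.channels[k]) / 2.0
                     for k in keys}
    return bino


def summarize_trial(events_by_eye: Mapping[str, Sequence[GazeEvent]],
                    stream: SampleStream, meta: TrialMeta,
                    geometry: DisplayGeometry = DEFAULT_GEOMETRY,
                    ) -> TrialRecord:
    """Reduce one trial's detected events to a :class:`TrialRecord`.

    Per-eye indicators are computed first; the binocular vector is the
    arithmetic mean of the two eyes' values where both are defined.
    """
    if len(stream) == 0:
        raise ValueError("empty sample stream")
    per_eye = {eye: _eye_indicators(events_by_eye.get(eye, ()), stream,
                                    eye, geometry) for eye in EYES}
    return TrialRecord(meta, per_eye,
                       _binocular_merge(per_eye["left"], per_eye["right"]))


# ---------------------------------------------------------------------------
# Outlier rejection

@dataclass
class OutlierResult:
    kept: np.ndarray
    removed_indices: np.ndarray
    rules: dict[int, tuple[str, ...]]   # index -> which rule(s) fired
    warned: bool = False                # too few values, passed through


def remove_outliers(values, iqr_factor: float = 1.5,
                    sigma: float = 3.0) -> OutlierResult:
    """Union of box-plot (1.5 IQR) and 3-sigma outlier rejection.

    Values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` or beyond
    ``mean +- sigma*SD`` (sample SD) are removed; each removal records
    which rule(s) fired.  Fewer than 4 values pass through with a warning
    flag.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 4:
        return OutlierResult(arr.copy(), np.array([], dtype=int), {}, True)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    mean, sd = arr.mean(), arr.std(ddof=1)
    rules: dict[int, tuple[str, ...]] = {}
    for i, v in enumerate(arr):
        fired = []
        if v < lo or v > hi:
            fired.append("iqr")
        if sd > 0 and abs(v - mean) > sigma * sd:
            fired.append("sigma")
        if fired:
            rules[i] = tuple(fired)
    removed = np.array(sorted(rules), dtype=int)
    keep_mask = np.ones(arr.size, dtype=bool)
    keep_mask[removed] = False
    return OutlierResult(arr[keep_mask], removed, rules)


def percent_normalize(group_means) -> np.ndarray:
    """Share-of-total percentages for three group means (sums to 100)."""
    arr = np.asarray(group_means, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected exactly three group means")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("group means must be defined and non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("zero total")
    return arr / total * 100.0


# ---------------------------------------------------------------------------
# Tables

def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def aggregate_repetitions(trials: pd.DataFrame) -> pd.DataFrame:
    """Average the repetitions into one row per subject x paradigm x group.

    This is the unit of analysis for the group statistics and the z-score
    pools (one value per subject per group, 36 fusion + 18 rivalry units
    per paradigm in the 18-subject design).
    """
    keys = ["subject_id", "paradigm", "group", "state"]
    numeric = trials.select_dtypes(include=[np.number]).columns
    numeric = [c for c in numeric if c != "repetition"]
    return (trials.groupby(keys, sort=True, as_index=False)[list(numeric)]
            .mean())


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
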