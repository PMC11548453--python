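"""Recording I/O, clock synchronization and IMU/annotation fusion.

A trial produces two files on different clocks: a 200 Hz 6-axis IMU trace
(device clock) and a 60 fps foot-status/activity annotation table (trial
clock, t=0 at the third synchronization heel strike).  This module reads
and writes both as CSV, locates the heel-strike prelude to re-base the IMU
clock, and fuses the two into the 11-column "enriched" dataset used by the
classifier: time, 3-axis accelerations, 3-axis angular rates, acceleration
norm, gyroscope norm, foot status, and activity code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ACC_RANGE_G",
    "GYRO_RANGE_DPS",
    "FormatError",
    "SyncError",
    "ImuRecording",
    "AnnotationTable",
    "EnrichedRecording",
    "read_imu_csv",
    "write_imu_csv",
    "read_annotation_csv",
    "write_annotation_csv",
    "compute_norms",
    "detect_sync_strikes",
    "rebase",
    "align_annotations",
    "drop_undetermined",
]

#: accelerometer full-scale range (g)
ACC_RANGE_G = 16.0
#: gyroscope full-scale range (°/s)
GYRO_RANGE_DPS = 2000.0

IMU_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
ACC_COLUMNS = ["acc_x", "acc_y", "acc_z"]
GYRO_COLUMNS = ["gyro_x", "gyro_y", "gyro_z"]
NORM_COLUMNS = ["acc_norm", "gyro_norm"]
ANNOTATION_COLUMNS = ["time_s", "foot_status", "activity"]
ENRICHED_COLUMNS = (
    ["time_s"] + ACC_COLUMNS + GYRO_COLUMNS + NORM_COLUMNS + ["foot_status", "activity"]
)
#: the 8 candidate input channels ranked during data reduction
CANDIDATE_CHANNELS = ACC_COLUMNS + GYRO_COLUMNS + NORM_COLUMNS


class FormatError(ValueError):
    """A recording file violates the declared column set or invariants."""


class SyncError(RuntimeError):
    """The heel-strike synchronization prelude could not be located."""


def _check_range(frame: pd.DataFrame, columns: list[str], limit: float) -> None:
    for col in columns:
        vals = frame[col].to_numpy()
        bad = np.flatnonzero(np.abs(vals) > limit)
        if bad.size:
            raise FormatError(
                f"column {col!r} row {bad[0]}: value {vals[bad[0]]:g} outside ±{limit:g}"
            )


@dataclass
class ImuRecording:
    """Uniformly sampled 6-axis inertial trace, optionally with derived norms."""

    frame: pd.DataFrame
    fs: float = 200.0

    def __post_init__(self) -> None:
        missing = [c for c in IMU_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"IMU recording missing columns {missing}")
        t = self.frame["time_s"].to_numpy()
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise FormatError(f"column 'time_s' row {row}: time not strictly increasing")
        _check_range(self.frame, ACC_COLUMNS, ACC_RANGE_G)
        _check_range(self.frame, GYRO_COLUMNS, GYRO_RANGE_DPS)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AnnotationTable:
    """Frame-rate (≈60 fps) foot-status and activity labels."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"annotation table missing columns {missing}")
        status = self.frame["foot_status"].to_numpy()
        bad = np.flatnonzero(~np.isin(status, (0, 1, 2)))
        if bad.size:
            raise FormatError(
                f"column 'foot_status' row {bad[0]}: value {status[bad[0]]} not in {{0,1,2}}"
            )
        t = self.frame["time_s"].to_numpy()
        if t.size >= 2 and np.any(np.diff(t) < 0):
            row = int(np.flatnonzero(np.diff(t) < 0)[0]) + 1
            raise FormatError(f"column 'time_s' row {row}: time decreasing")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class EnrichedRecording:
    """Sample-level fusion of IMU and annotation: exactly 11 columns."""

    frame: pd.DataFrame
    fs: float = 200.0

    def __post_init__(self) -> None:
        missing = [c for c in ENRICHED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"enriched recording missing columns {missing}")
        extra = [c for c in self.frame.columns if c not in ENRICHED_COLUMNS]
        if extra:
            self.frame = self.frame[ENRICHED_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def determined_mask(self) -> np.ndarray:
        """True where the foot status was determinable from the video."""
        return self.frame["foot_status"].to_numpy() != 2


def read_imu_csv(path, fs: float = 200.0) -> ImuRecording:
    frame = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return ImuRecording(frame, fs=fs)


def write_imu_csv(rec: ImuRecording, path) -> None:
    cols = [c for c in IMU_COLUMNS + NORM_COLUMNS if c in rec.frame.columns]
    rec.frame[cols].to_csv(path, index=False, float_format="%.6f")


def read_annotation_csv(path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path))


def write_annotation_csv(ann: AnnotationTable, path) -> None:
    ann.frame[ANNOTATION_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def compute_norms(rec: ImuRecording) -> ImuRecording:
    """Attach Euclidean acceleration and angular-rate norms per sample."""
    frame = rec.frame.copy()
    acc = frame[ACC_COLUMNS].to_numpy()
    gyro = frame[GYRO_COLUMNS].to_numpy()
    if not (np.all(np.isfinite(acc)) and np.all(np.isfinite(gyro))):
        raise FormatError("non-finite sensor values")
    frame["acc_norm"] = np.linalg.norm(acc, axis=1)
    frame["gyro_norm"] = np.linalg.norm(gyro, axis=1)
    return ImuRecording(frame, fs=rec.fs)


def detect_sync_strikes(rec: ImuRecording, min_peak: float = 2.0,
                        min_separation_ms: float = 200.0) -> float:
    """Locate the third synchronization heel strike; its time defines t0.

    Peaks of the acceleration norm above ``min_peak`` are scanned left to
    right; a peak closer than ``min_separation_ms`` to the previously
    accepted one is treated as part of the same impact.
    """
    frame = rec.frame
    if "acc_norm" not in frame.columns:
        frame = compute_norms(rec).frame
    acc_norm = frame["acc_norm"].to_numpy()
    t = frame["time_s"].to_numpy()
    cand, _ = find_peaks(acc_norm, height=min_peak)
    sep_s = min_separation_ms / 1000.0
    accepted: list[int] = []
    for idx in cand:
        if not accepted or t[idx] - t[accepted[-1]] >= sep_s:
            accepted.append(int(idx))
        if len(accepted) == 3:
            return float(t[accepted[2]])
    raise SyncError(
        f"found only {len(accepted)} qualifying heel strikes "
        f"(need 3 with peaks > {min_peak} g, separated by ≥ {min_separation_ms} ms)"
    )


def rebase(rec: ImuRecording, t0: float) -> ImuRecording:
    """Shift the recording onto the trial clock (t0 becomes time 0)."""
    frame = rec.frame.copy()
    frame["time_s"] = frame["time_s"] - t0
    return ImuRecording(frame, fs=rec.fs)


def align_annotations(rec: ImuRecording, ann: AnnotationTable) -> EnrichedRecording:
    """Fuse IMU samples with annotation frames into the 11-column dataset.

    Both inputs must share the trial clock.  Each IMU sample inherits the
    foot status and activity of the latest annotation frame at or before
    it (sample-and-hold); samples outside the annotated span are dropped.
    """
    if len(ann) == 0:
        raise ValueError("empty annotation table")
    frame = rec.frame
    if "acc_norm" not in frame.columns:
        frame = compute_norms(rec).frame
    t = frame["time_s"].to_numpy()
    ta = ann.frame["time_s"].to_numpy()
    keep = (t >= ta[0] - 1e-9) & (t <= ta[-1] + 1e-9)
    sub = frame.loc[keep].reset_index(drop=True)
    idx = np.searchsorted(ta, sub["time_s"].to_numpy() + 1e-9, side="right") - 1
    sub["foot_status"] = ann.frame["foot_status"].to_numpy()[idx]
    sub["activity"] = ann.frame["activity"].to_numpy()[idx]
    return EnrichedRecording(sub[ENRICHED_COLUMNS], fs=rec.fs)


def drop_undetermined(enr: EnrichedRecording) -> EnrichedRecording:
    """Remove rows whose foot status is undetermined (label 2).

    Used for correlation ranking and metrics; window construction instead
    works on the full frame and consults :attr:`EnrichedRecording.determined_mask`
    so that sensor history inside windows respects the original timeline.
    """
    mask = enr.determined_mask
    if not mask.any():
        warnings.warn("all samples undetermined; result is empty", stacklevel=2)
    return EnrichedRecording(enr.frame.loc[mask].reset_index(drop=True), fs=enr.fs)
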