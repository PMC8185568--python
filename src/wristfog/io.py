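"""Reading and writing wrist-IMU recordings and interval annotations.

Two plain-text formats are used throughout the package:

* **Recording CSV** — header ``t,ax,ay,az,gx,gy,gz`` (the ``t`` column is
  optional), one row per sample.  ``ax..az`` are tri-axial accelerometer
  channels, ``gx..gz`` tri-axial gyroscope channels.  The sample index is
  authoritative; a time column, when present, is only checked for
  consistency with the declared sampling rate and never used for indexing.
* **Annotation CSV** — header ``start_s,end_s,label`` with labels drawn
  from ``FOG | STOP | WALK`` (case-insensitive on read, upper-case on
  write).  Intervals must be sorted, non-overlapping and of positive
  length.

Units (g or m/s² for acceleration, deg/s for angular rate) are carried as
metadata only: the downstream pipeline normalizes every channel by its
cohort-wide maximum, so absolute scale never matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed class order used everywhere in the package (serialization,
#: probability vectors, confusion matrices).
LABELS: tuple[str, str, str] = ("FOG", "STOP", "WALK")

#: Channel order of the N×6 sample matrix.
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

DEFAULT_FS = 128.0


class ImuFormatError(ValueError):
    """Raised when a recording or annotation file violates its format."""


@dataclass
class ImuRecording:
    """One subject's continuous 6-channel IMU recording.

    ``samples`` is an N×6 float matrix in channel order
    ``(ax, ay, az, gx, gy, gz)``; ``fs`` is the sampling rate in Hz.
    """

    subject_id: str
    samples: np.ndarray
    fs: float = DEFAULT_FS
    units: dict = field(default_factory=lambda: {"accel": "g", "gyro": "deg/s"})

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ImuFormatError(
                f"samples must be N×6, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ImuFormatError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ImuFormatError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(self.samples).all():
            raise ImuFormatError("recording contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labeled intervals covering a session.

    ``intervals`` is a list of ``(start_s, end_s, label)`` tuples with
    ``label`` in :data:`LABELS`.  Intervals are treated as half-open
    ``[start_s, end_s)`` throughout the package.
    """

    subject_id: str
    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        cleaned = []
        for i, (start, end, label) in enumerate(self.intervals):
            label = str(label).upper()
            if label not in LABELS:
                raise ImuFormatError(
                    f"interval {i}: unknown label {label!r}, expected one of {LABELS}"
                )
            if not float(start) < float(end):
                raise ImuFormatError(
                    f"interval {i}: start_s ({start}) must be < end_s ({end})"
                )
            cleaned.append((float(start), float(end), label))
        for i in range(1, len(cleaned)):
            prev, cur = cleaned[i - 1], cleaned[i]
            if cur[0] < prev[0]:
                raise ImuFormatError(
                    f"intervals not sorted by start_s: {prev[:2]} then {cur[:2]}"
                )
            if cur[0] < prev[1]:
                raise ImuFormatError(
                    f"overlapping intervals {prev[:2]} and {cur[:2]}"
                )
        self.intervals = cleaned

    @property
    def coverage(self) -> tuple[float, float]:
        """(earliest start, latest end) over all intervals."""
        if not self.intervals:
            raise ImuFormatError("annotation track is empty")
        return self.intervals[0][0], max(e for _, e, _ in self.intervals)


def read_recording(path, fs: float = DEFAULT_FS, subject_id: str | None = None) -> ImuRecording:
    """Read a recording CSV (6 or 7 columns) into an :class:`ImuRecording`.

    If a ``t`` column is present, the median sample spacing is checked
    against ``1/fs``; a deviation beyond 1% raises a warning (not an
    error — the sample index remains authoritative).  A non-numeric or
    missing cell is an error naming the offending data row (1-based).
    """
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    if cols == ["t", *CHANNELS]:
        has_time = True
    elif cols == list(CHANNELS):
        has_time = False
    else:
        raise ImuFormatError(
            f"{path}: expected header {('t',) + CHANNELS} or {CHANNELS}, got {tuple(cols)}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ImuFormatError(f"{path}: malformed or missing value at data row {row}")
    if has_time:
        t = numeric["t"].to_numpy()
        if len(t) > 1:
            spacing = float(np.median(np.diff(t)))
            if abs(spacing - 1.0 / fs) > 0.01 / fs:
                warnings.warn(
                    f"{path}: median sample spacing {spacing:.6f}s deviates from "
                    f"1/fs={1.0 / fs:.6f}s by more than 1%",
                    stacklevel=2,
                )
    samples = numeric[list(CHANNELS)].to_numpy(dtype=float)
    if subject_id is None:
        subject_id = _stem(path)
    return ImuRecording(subject_id=subject_id, samples=samples, fs=fs)


def write_recording(recording: ImuRecording, path, decimals: int = 4,
                    include_time: bool = False) -> None:
    """Write a recording CSV rounded to ``decimals`` decimal digits.

    Round-trips exactly at the declared precision (half-to-even rounding).
    """
    data = {}
    if include_time:
        data["t"] = np.arange(recording.n_samples) / recording.fs
    for i, c in enumerate(CHANNELS):
        data[c] = recording.samples[:, i]
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def read_annotations(path, subject_id: str | None = None) -> AnnotationTrack:
    """Read an annotation CSV (``start_s,end_s,label``) into a validated track."""
    df = pd.read_csv(path)
    expected = ["start_s", "end_s", "label"]
    if [c.strip() for c in df.columns] != expected:
        raise ImuFormatError(f"{path}: expected header {expected}, got {list(df.columns)}")
    intervals = [
        (row.start_s, row.end_s, row.label) for row in df.itertuples(index=False)
    ]
    if subject_id is None:
        subject_id = _stem(path)
    return AnnotationTrack(subject_id=subject_id, intervals=intervals)


def write_annotations(track: AnnotationTrack, path) -> None:
    df = pd.DataFrame(track.intervals, columns=["start_s", "end_s", "label"])
    df.to_csv(path, index=False)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
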