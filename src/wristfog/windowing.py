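"""Normalization, sliding-window segmentation and window labeling.

The preprocessing pipeline mirrors the standard wearable-sensor recipe for
freezing-of-gait detection from a single wrist IMU:

1. every channel is divided by its maximum absolute value across the whole
   cohort (so the training-set extreme maps to ±1) and rounded to four
   decimal digits;
2. each recording is cut into 3 s windows advanced by a 0.25 s step
   (at 128 Hz: 384 samples, step 32), giving one class decision every
   0.25 s in streaming use;
3. each window is labeled FOG / STOP / WALK from the interval annotations.

The FOG labeling rule is asymmetric on purpose, because half of real FoG
episodes last under 3 s: a window is FOG if (a) an entire episode falls
inside it, however short, or (b) the FoG content of the window reaches
half the window length (1.5 s at defaults).  Otherwise the window takes
the majority non-FoG class, ties going to WALK.  All intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import LABELS, AnnotationTrack, ImuRecording

logger = logging.getLogger(__name__)

#: How rule (b) measures "the duration of the FoG":
#: * ``"window_overlap"`` (default) — total FoG time inside the window;
#: * ``"episode_duration"`` — the overlapping episode's own full duration.
FOG_RULES = ("window_overlap", "episode_duration")


@dataclass
class WindowConfig:
    """Sliding-window geometry: 3 s windows, 0.25 s step, 128 Hz defaults."""

    window_s: float = 3.0
    step_s: float = 0.25
    fs: float = 128.0
    fog_rule: str = "window_overlap"

    def __post_init__(self) -> None:
        if self.fog_rule not in FOG_RULES:
            raise ValueError(f"fog_rule must be one of {FOG_RULES}")
        if not (self.window_n >= self.step_n >= 1):
            raise ValueError(
                f"need window_n >= step_n >= 1, got {self.window_n}, {self.step_n}"
            )

    @property
    def window_n(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def step_n(self) -> int:
        return int(round(self.step_s * self.fs))


@dataclass
class NormalizationScale:
    """Per-channel cohort-wide max-absolute-value scale factors (length 6)."""

    scales: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.shape != (6,):
            raise ValueError(f"expected 6 per-channel scales, got {self.scales.shape}")
        if not (self.scales > 0).all():
            raise ValueError("all scale factors must be positive")


@dataclass
class LabeledWindow:
    """A single normalized window with its class label and provenance."""

    subject_id: str
    start_index: int
    data: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def compute_cohort_scales(recordings: list[ImuRecording]) -> NormalizationScale:
    """Maximum absolute value per channel across every cohort recording.

    The max-abs (rather than plain max) keeps signed data inside [-1, 1].
    An all-zero channel across the cohort is an error: its scale would be
    undefined.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    stacked = np.vstack([r.samples for r in recordings])
    scales = np.abs(stacked).max(axis=0)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        from .io import CHANNELS

        names = [CHANNELS[i] for i in zero]
        raise ValueError(f"channel(s) {names} are all-zero across the cohort")
    return NormalizationScale(scales)


def normalize(recording: ImuRecording, scales: NormalizationScale,
              decimals: int = 4) -> ImuRecording:
    """Divide each channel by its cohort scale and round (half-to-even).

    The channel attaining the cohort maximum maps to exactly ±1.0; all
    values end up in [-1, 1] up to the rounding quantum.
    """
    values = np.round(recording.samples / scales.scales, decimals)
    return ImuRecording(
        subject_id=recording.subject_id,
        samples=values,
        fs=recording.fs,
        units={"accel": "normalized", "gyro": "normalized"},
    )


def count_windows(n_samples: int, config: WindowConfig) -> int:
    """Number K of sliding windows in a recording of ``n_samples`` samples.

    K = floor((N - window_n) / step_n) + 1, or 0 when the recording is
    shorter than one window.
    """
    if n_samples < config.window_n:
        return 0
    return (n_samples - config.window_n) // config.step_n + 1


def segment(recording: ImuRecording, config: WindowConfig) -> list[tuple[int, np.ndarray]]:
    """Cut a recording into (start_index, window_n×6 matrix) pairs.

    Window k starts at sample ``k * step_n``; contents are exact row
    slices of the recording (views, not copies).
    """
    k = count_windows(recording.n_samples, config)
    w, s = config.window_n, config.step_n
    return [(i * s, recording.samples[i * s:i * s + w]) for i in range(k)]


def _overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Length of the intersection of two half-open intervals."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def label_window(window_span: tuple[float, float], track: AnnotationTrack,
                 config: WindowConfig) -> str:
    """Assign FOG / STOP / WALK to the window spanning ``(start_s, end_s)``.

    FOG wins if any episode is fully contained in the window (any
    duration), or if the FoG duration criterion meets half the window
    length (see :data:`FOG_RULES`).  Otherwise the non-FoG class with the
    larger in-window overlap wins; ties break as WALK.
    """
    w_start, w_end = window_span
    cov_start, cov_end = track.coverage
    if w_start < cov_start - 1e-9 or w_end > cov_end + 1e-9:
        raise ValueError(
            f"window {window_span} outside annotation coverage ({cov_start}, {cov_end})"
        )
    half_window = config.window_s / 2.0

    fog_overlap_total = 0.0
    fog_hit = False
    other_overlap = {"STOP": 0.0, "WALK": 0.0}
    for start, end, label in track.intervals:
        ov = _overlap(w_start, w_end, start, end)
        if label == "FOG":
            if ov <= 0:
                continue
            if start >= w_start and end <= w_end:  # episode fully inside
                fog_hit = True
            fog_overlap_total += ov
            if config.fog_rule == "episode_duration" and (end - start) >= half_window:
                fog_hit = True
        elif ov > 0:
            other_overlap[label] += ov
    if config.fog_rule == "window_overlap" and fog_overlap_total >= half_window - 1e-9:
        fog_hit = True
    if fog_hit:
        return "FOG"
    # majority of the remaining classes; tie -> WALK
    if other_overlap["STOP"] > other_overlap["WALK"]:
        return "STOP"
    return "WALK"


def build_dataset(recordings: list[ImuRecording], tracks: list[AnnotationTrack],
                  config: WindowConfig | None = None,
                  scales: NormalizationScale | None = None) -> tuple[list[LabeledWindow], NormalizationScale]:
    """Normalize a cohort, segment every recording and label every window.

    ``tracks`` must match ``recordings`` one-to-one by subject id.  When
    ``scales`` is omitted it is computed from the cohort itself (the
    training-time convention); pass stored scales for held-out data.
    Returns the labeled windows plus the scales used.
    """
    config = config or WindowConfig()
    if len(recordings) != len(tracks):
        raise ValueError("need one annotation track per recording")
    by_subject = {t.subject_id: t for t in tracks}
    for rec in recordings:
        if rec.subject_id not in by_subject:
            raise ValueError(f"no annotation track for subject {rec.subject_id!r}")
    if scales is None:
        scales = compute_cohort_scales(recordings)

    windows: list[LabeledWindow] = []
    counts = dict.fromkeys(LABELS, 0)
    for rec in recordings:
        track = by_subject[rec.subject_id]
        norm = normalize(rec, scales)
        for start, data in segment(norm, config):
            span = (start / config.fs, (start + config.window_n) / config.fs)
            label = label_window(span, track, config)
            windows.append(LabeledWindow(rec.subject_id, start, data, label))
            counts[label] += 1
    logger.info(
        "built dataset: %d windows from %d subjects (%s)",
        len(windows), len(recordings),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return windows, scales


def save_dataset(windows: list[LabeledWindow], manifest_path, matrix_path) -> None:
    """Export a windowed dataset: CSV manifest + NPZ matrix store.

    The manifest has columns ``subject_id,start_index,label``, row i of
    which describes slice i of the ``windows`` array in the NPZ file.
    """
    import pandas as pd

    df = pd.DataFrame(
        [(w.subject_id, w.start_index, w.label) for w in windows],
        columns=["subject_id", "start_index", "label"],
    )
    df.to_csv(manifest_path, index=False)
    np.savez_compressed(matrix_path, windows=np.stack([w.data for w in windows]))


def load_dataset(manifest_path, matrix_path) -> list[LabeledWindow]:
    import pandas as pd

    df = pd.read_csv(manifest_path)
    mats = np.load(matrix_path)["windows"]
    if len(df) != len(mats):
        raise ValueError("manifest and matrix store disagree on window count")
    return [
        LabeledWindow(row.subject_id, int(row.start_index), mats[i], row.label)
        for i, row in enumerate(df.itertuples(index=False))
    ]
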