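"""Hand-crafted time/frequency features and classical baselines.

The feature vector is the canonical single-sensor freezing-of-gait set:
per channel, the statistical moments (mean, SD, variance, min, max, RMS,
energy) plus spectral descriptors computed from a rectangular-window
periodogram of the mean-removed channel — spectral entropy, dominant
frequency, band power in the locomotor band (0.5–3 Hz), band power in
the freeze band (3–8 Hz), and the freeze index (freeze-band power over
locomotor-band power), the classical FoG discriminant.  The same
spectral descriptors are also computed on the acceleration- and
angular-rate-magnitude signals, which are insensitive to wrist
orientation.

Two baseline classifiers consume these features through the same
predict interface as the CNN: a decision tree and gradient-boosted
trees (XGBoost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .io import CHANNELS, LABELS
from .windowing import LabeledWindow

logger = logging.getLogger(__name__)

LOCOMOTOR_BAND = (0.5, 3.0)
FREEZE_BAND = (3.0, 8.0)

_STAT_NAMES = ("mean", "std", "var", "min", "max", "rms", "energy")
_SPEC_NAMES = ("spec_entropy", "dom_freq", "loco_power", "freeze_power", "freeze_index")


def feature_names() -> list[str]:
    names = []
    for ch in CHANNELS:
        names += [f"{ch}_{s}" for s in _STAT_NAMES + _SPEC_NAMES]
    for sensor in ("accel_mag", "gyro_mag"):
        names += [f"{sensor}_{s}" for s in _SPEC_NAMES]
    return names


FEATURE_NAMES = feature_names()


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integrated PSD over [lo, hi] (trapezoid, with interpolated edges).

    Using exact band edges (rather than nearest-bin sums) makes a flat
    spectrum integrate to power-density × bandwidth, so band-power ratios
    equal bandwidth ratios for white noise.
    """
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = (freqs > lo) & (freqs < hi)
    f_band = np.concatenate(([lo], freqs[inner], [hi]))
    p_band = np.concatenate((
        [np.interp(lo, freqs, psd)], psd[inner], [np.interp(hi, freqs, psd)]
    ))
    return float(np.trapezoid(p_band, f_band))


def _spectral_features(x: np.ndarray, fs: float,
                       bands=(LOCOMOTOR_BAND, FREEZE_BAND)) -> tuple[float, ...]:
    """(entropy, dominant freq, loco power, freeze power, freeze index)."""
    if np.var(x) == 0:
        logger.debug("zero-variance channel: spectral features defined as 0")
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    freqs, psd = periodogram(x, fs=fs, window="boxcar", detrend="constant")
    total = psd.sum()
    p = psd / total
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum() / np.log2(len(psd)))
    dom = float(freqs[int(np.argmax(psd))])
    loco = band_power(freqs, psd, *bands[0])
    freeze = band_power(freqs, psd, *bands[1])
    fi = freeze / loco if loco > 0 else 0.0
    return (entropy, dom, loco, freeze, fi)


def extract_features(window: np.ndarray, fs: float = 128.0) -> np.ndarray:
    """Feature vector for one window_n×6 window (order per FEATURE_NAMES)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 6:
        raise ValueError(f"expected L×6 window, got {window.shape}")
    if window.shape[0] < 64:
        raise ValueError("window too short for spectral estimation (need >= 64 samples)")
    feats: list[float] = []
    for c in range(6):
        x = window[:, c]
        feats += [
            float(x.mean()), float(x.std()), float(x.var()),
            float(x.min()), float(x.max()),
            float(np.sqrt(np.mean(x ** 2))), float(np.sum(x ** 2)),
        ]
        feats += list(_spectral_features(x, fs))
    accel_mag = np.linalg.norm(window[:, :3], axis=1)
    gyro_mag = np.linalg.norm(window[:, 3:], axis=1)
    feats += list(_spectral_features(accel_mag, fs))
    feats += list(_spectral_features(gyro_mag, fs))
    return np.asarray(feats)


def extract_feature_matrix(windows: list[LabeledWindow], fs: float = 128.0):
    """(feature matrix, label array) for a window list."""
    x = np.stack([extract_features(w.data, fs) for w in windows])
    y = np.array([LABELS.index(w.label) for w in windows])
    return x, y


def feature_table(windows: list[LabeledWindow], fs: float = 128.0):
    """One-row-per-window DataFrame: subject_id, start_index, label, features."""
    import pandas as pd

    x, _ = extract_feature_matrix(windows, fs)
    meta = pd.DataFrame(
        [(w.subject_id, w.start_index, w.label) for w in windows],
        columns=["subject_id", "start_index", "label"],
    )
    return pd.concat([meta, pd.DataFrame(x, columns=FEATURE_NAMES)], axis=1)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

BASELINE_KINDS = ("decision_tree", "gradient_boosting")


@dataclass
class BaselineModel:
    """A fitted feature-based classifier with the CNN's predict interface."""

    kind: str
    estimator: object
    fs: float = 128.0

    def predict_proba_windows(self, windows: list[LabeledWindow]) -> np.ndarray:
        x, _ = extract_feature_matrix(windows, self.fs)
        return self.estimator.predict_proba(x)

    def predict_class_windows(self, windows: list[LabeledWindow]) -> list[str]:
        probs = self.predict_proba_windows(windows)
        return [LABELS[i] for i in np.argmax(probs, axis=1)]


def train_baseline(features: np.ndarray, labels: np.ndarray, kind: str,
                   seed: int = 0, fs: float = 128.0) -> BaselineModel:
    """Fit a decision tree or gradient-boosting baseline on feature rows.

    Hyperparameters are the library defaults (logged); ``labels`` are
    integer indices into LABELS.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"kind must be one of {BASELINE_KINDS}")
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("baseline training needs at least 2 classes")
    if np.all(features.std(axis=0) == 0):
        raise ValueError("degenerate feature matrix: every column is constant")
    if kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        est = DecisionTreeClassifier(random_state=seed)
    else:
        from xgboost import XGBClassifier

        est = XGBClassifier(
            objective="multi:softprob", num_class=3, random_state=seed,
            n_estimators=100, verbosity=0,
        )
    est.fit(features, labels)
    logger.info("fitted %s baseline: %s", kind, est.get_params())
    return BaselineModel(kind=kind, estimator=_wrap_classes(est, labels))


class _wrap_classes:
    """Expand predict_proba to all 3 classes even if training saw fewer.

    XGBoost/sklearn order probabilities by the classes present in ``fit``;
    this shim pins columns to the global LABELS index.
    """

    def __init__(self, est, labels):
        self.est = est
        self.classes_seen = np.unique(labels)

    def predict_proba(self, x):
        raw = self.est.predict_proba(x)
        out = np.zeros((len(x), len(LABELS)))
        for j, cls in enumerate(self.classes_seen):
            out[:, int(cls)] = raw[:, j]
        return out
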