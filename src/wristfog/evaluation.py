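"""Cross-validation schemes and FoG-class detection metrics.

Two protocols are implemented:

* **leave-one-subject-out (LOSO)** — one fold per subject; each fold
  trains on every other subject's windows and tests on all of the held
  out subject's windows.  This estimates generalization to a new
  patient, the clinically relevant question.
* **shuffled 10-fold** — window-level shuffling, subject-agnostic.
  Because neighbouring windows overlap by 2.75 s, train and test folds
  share nearly identical windows; the scheme is reported for comparison
  with common practice, and a subject-stratified variant is available
  behind a flag for a more honest split.

Metrics treat FOG as the positive class one-vs-rest: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1, plus a macro-F1 over the three
classes.  A zero-denominator metric is reported as ``None`` (undefined),
never coerced to 0.  Aggregate LOSO metrics are computed both from the
pooled confusion matrix and as unweighted per-subject means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import LABELS
from .windowing import LabeledWindow

logger = logging.getLogger(__name__)

_POS = {label: i for i, label in enumerate(LABELS)}


def confusion_matrix3(y_true: list[str], y_pred: list[str]) -> np.ndarray:
    """3×3 counts, rows = true class, columns = predicted, order LABELS."""
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        cm[_POS[t], _POS[p]] += 1
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (3, 3) or (cm < 0).any():
        raise ValueError("confusion matrix must be 3×3 with nonnegative counts")
    return cm


def sensitivity_specificity(cm: np.ndarray, positive: str = "FOG"):
    """One-vs-rest (sensitivity, specificity); undefined values are None."""
    cm = _check_cm(cm)
    i = _POS[positive]
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if sens is None or spec is None:
        logger.warning("undefined metric for class %s (zero denominator)", positive)
    return sens, spec


def f_score(cm: np.ndarray, positive: str = "FOG"):
    """One-vs-rest F1 for ``positive``; None when precision and recall are undefined."""
    cm = _check_cm(cm)
    i = _POS[positive]
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    if tp + fn == 0 and tp + fp == 0:
        logger.warning("undefined F-score for class %s", positive)
        return None
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def macro_f_score(cm: np.ndarray):
    """Unweighted mean F1 over the three classes (defined classes only)."""
    scores = [f_score(cm, label) for label in LABELS]
    defined = [s for s in scores if s is not None]
    return float(np.mean(defined)) if defined else None


@dataclass
class EvalReport:
    """Per-fold confusion matrices plus derived aggregate metrics."""

    scheme: str
    fold_names: list[str]
    fold_cms: list[np.ndarray]
    seed: int
    assignments: dict[str, list] = field(default_factory=dict)

    @property
    def pooled_cm(self) -> np.ndarray:
        return np.sum(self.fold_cms, axis=0)

    def fold_metrics(self) -> list[dict]:
        rows = []
        for name, cm in zip(self.fold_names, self.fold_cms):
            sens, spec = sensitivity_specificity(cm)
            rows.append({
                "fold": name, "n": int(cm.sum()),
                "sensitivity": sens, "specificity": spec,
                "fog_f1": f_score(cm), "macro_f1": macro_f_score(cm),
            })
        return rows

    def aggregate(self) -> dict:
        sens, spec = sensitivity_specificity(self.pooled_cm)
        per_fold = self.fold_metrics()
        mean_of = lambda key: (
            float(np.mean([r[key] for r in per_fold if r[key] is not None]))
            if any(r[key] is not None for r in per_fold) else None
        )
        return {
            "pooled": {
                "sensitivity": sens, "specificity": spec,
                "fog_f1": f_score(self.pooled_cm),
                "macro_f1": macro_f_score(self.pooled_cm),
            },
            "fold_mean": {
                "sensitivity": mean_of("sensitivity"),
                "specificity": mean_of("specificity"),
                "fog_f1": mean_of("fog_f1"),
                "macro_f1": mean_of("macro_f1"),
            },
        }

    def to_json(self, path=None) -> str:
        payload = {
            "scheme": self.scheme, "seed": self.seed,
            "labels": list(LABELS),
            "folds": [
                {"name": n, "confusion": cm.tolist()}
                for n, cm in zip(self.fold_names, self.fold_cms)
            ],
            "fold_metrics": self.fold_metrics(),
            "aggregate": self.aggregate(),
            "assignments": self.assignments,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            f"## {self.scheme} evaluation (seed {self.seed})", "",
            "| fold | n | sensitivity | specificity | FoG F1 | macro F1 |",
            "|---|---|---|---|---|---|",
        ]
        fmt = lambda v: "–" if v is None else f"{v:.3f}"
        for r in self.fold_metrics():
            lines.append(
                f"| {r['fold']} | {r['n']} | {fmt(r['sensitivity'])} | "
                f"{fmt(r['specificity'])} | {fmt(r['fog_f1'])} | {fmt(r['macro_f1'])} |"
            )
        agg = self.aggregate()["pooled"]
        lines.append(
            f"| **pooled** | {int(self.pooled_cm.sum())} | {fmt(agg['sensitivity'])} | "
            f"{fmt(agg['specificity'])} | {fmt(agg['fog_f1'])} | {fmt(agg['macro_f1'])} |"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# trainers: uniform fitting interface over the CNN, the baselines and dummies
# ---------------------------------------------------------------------------


def cnn_trainer(model_config=None, train_config=None):
    """Trainer callable wrapping the CNN for use with the CV drivers."""
    from . import cnn as _cnn

    def fit(train_windows: list[LabeledWindow], seed: int):
        tcfg = train_config or _cnn.TrainConfig()
        tcfg = _cnn.TrainConfig(**{**tcfg.__dict__, "seed": seed})
        trained = _cnn.train(model_config, train_windows, tcfg)
        return lambda test_windows: _cnn.predict_class(
            trained, np.stack([w.data for w in test_windows]).astype(np.float32)
        )

    return fit


def baseline_trainer(kind: str, fs: float = 128.0):
    """Trainer callable wrapping a feature-based baseline."""
    from .features import extract_feature_matrix, train_baseline

    def fit(train_windows: list[LabeledWindow], seed: int):
        x, y = extract_feature_matrix(train_windows, fs)
        model = train_baseline(x, y, kind, seed=seed, fs=fs)
        return lambda test_windows: model.predict_class_windows(test_windows)

    return fit


def dummy_trainer(strategy: str = "majority"):
    """Majority-class or uniform-random dummy, for analytic control tests."""

    def fit(train_windows: list[LabeledWindow], seed: int):
        labels = [w.label for w in train_windows]
        if strategy == "majority":
            top = max(LABELS, key=labels.count)
            return lambda test_windows: [top] * len(test_windows)
        rng = np.random.default_rng(seed)
        return lambda test_windows: [
            LABELS[i] for i in rng.integers(0, 3, len(test_windows))
        ]

    return fit


# ---------------------------------------------------------------------------
# cross-validation drivers
# ---------------------------------------------------------------------------


def loso_cv(windows: list[LabeledWindow], trainer, seed: int = 0) -> EvalReport:
    """Leave-one-subject-out: one fold per subject, no window on both sides."""
    subjects = sorted({w.subject_id for w in windows})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    by_subject = {s: [w for w in windows if w.subject_id == s] for s in subjects}
    for s, ws in by_subject.items():
        if not ws:
            raise ValueError(f"subject {s} has zero windows")
    fold_cms, assignments = [], {}
    for s in subjects:
        test = by_subject[s]
        train_set = [w for w in windows if w.subject_id != s]
        predictor = trainer(train_set, seed)
        preds = predictor(test)
        fold_cms.append(confusion_matrix3([w.label for w in test], preds))
        assignments[s] = [int(w.start_index) for w in test]
        logger.info("LOSO fold %s: %d test windows", s, len(test))
    return EvalReport("loso", subjects, fold_cms, seed, assignments)


def kfold_cv(windows: list[LabeledWindow], trainer, k: int = 10, seed: int = 0,
             stratify_by_subject: bool = False) -> EvalReport:
    """Shuffled k-fold over windows; fold sizes differ by at most one.

    With ``stratify_by_subject`` each subject's windows are spread evenly
    over the folds (reduces — but does not eliminate — overlap leakage).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(windows):
        raise ValueError("k exceeds the number of windows")
    rng = np.random.default_rng(seed)
    n = len(windows)
    fold_of = np.empty(n, dtype=int)
    if stratify_by_subject:
        offset = 0
        for s in sorted({w.subject_id for w in windows}):
            idx = [i for i, w in enumerate(windows) if w.subject_id == s]
            idx = rng.permutation(idx)
            for j, i in enumerate(idx):
                fold_of[i] = (offset + j) % k
            offset += len(idx)
    else:
        perm = rng.permutation(n)
        for j, i in enumerate(perm):
            fold_of[i] = j % k
    fold_cms, names, assignments = [], [], {}
    for f in range(k):
        test_idx = np.flatnonzero(fold_of == f)
        train_set = [windows[i] for i in np.flatnonzero(fold_of != f)]
        test = [windows[i] for i in test_idx]
        predictor = trainer(train_set, seed)
        preds = predictor(test)
        fold_cms.append(confusion_matrix3([w.label for w in test], preds))
        names.append(f"fold{f}")
        assignments[f"fold{f}"] = [int(i) for i in test_idx]
        logger.info("k-fold %d/%d: %d test windows", f + 1, k, len(test))
    return EvalReport("kfold", names, fold_cms, seed, assignments)
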