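"""Per-class (one-vs-rest) and overall classification metrics.

For each class c the 4x4 confusion matrix is marginalized to one-vs-rest
tallies TP/FP/FN/TN, from which

    Acc = (TP + TN) / (TP + TN + FP + FN)        Pre = TP / (TP + FP)
    Sen = TP / (TP + FN)                          Spe = TN / (TN + FP)
    F1  = 2 * Pre * Sen / (Pre + Sen)

Per-class accuracy is the one-vs-rest accuracy (the only reading under
which per-class and overall accuracy can differ).  A 0/0 denominator
yields 0.0 and the affected (class, metric) pair is listed in
``MetricsReport.zero_denominator_flags``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ValidationError
from .io import LABELS

METRIC_NAMES = ("Acc", "Pre", "Sen", "Spe", "F1")


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> ConfusionMatrix:
    """counts[i, j] = number of records with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValidationError("y_true and y_pred must be equal-length 1-D")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes
        or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValidationError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.bincount(
        y_true * n_classes + y_pred, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float, flags: list, cls: str, name: str) -> float:
    if den == 0:
        flags.append((cls, name))
        return 0.0
    return num / den


@dataclasses.dataclass
class MetricsReport:
    """Per-class and overall metrics, all in [0, 1]."""

    per_class: dict  # label -> {Acc, Pre, Sen, Spe, F1}
    overall_accuracy: float
    zero_denominator_flags: list  # (label, metric) pairs resolved to 0 by convention
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "overall_accuracy": self.overall_accuracy,
            "zero_denominator_flags": [list(f) for f in self.zero_denominator_flags],
            "confusion_matrix": self.confusion.counts.tolist(),
        }

    def format_table(self) -> str:
        """Aligned-text table: one row per class, one column per metric."""
        lines = [f"{'Class':<8}" + "".join(f"{m:>8}" for m in METRIC_NAMES)]
        for lab, vals in self.per_class.items():
            lines.append(
                f"{lab:<8}" + "".join(f"{vals[m]:>8.3f}" for m in METRIC_NAMES)
            )
        lines.append(f"{'Overall':<8}{self.overall_accuracy:>8.3f}")
        return "\n".join(lines)


def one_vs_rest_tallies(cm: ConfusionMatrix, c: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for class ``c`` against all others."""
    counts = cm.counts
    tp = int(counts[c, c])
    fp = int(counts[:, c].sum()) - tp
    fn = int(counts[c, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def metrics_from_tallies(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Metric values from explicit one-vs-rest tallies (no flags)."""
    flags: list = []
    pre = _safe_div(tp, tp + fp, flags, "", "Pre")
    sen = _safe_div(tp, tp + fn, flags, "", "Sen")
    return {
        "Acc": _safe_div(tp + tn, tp + tn + fp + fn, flags, "", "Acc"),
        "Pre": pre,
        "Sen": sen,
        "Spe": _safe_div(tn, tn + fp, flags, "", "Spe"),
        "F1": _safe_div(2 * pre * sen, pre + sen, flags, "", "F1"),
    }


def metrics_report(cm: ConfusionMatrix, labels: tuple[str, ...] = LABELS) -> MetricsReport:
    """Full per-class + overall report from a confusion matrix."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    if cm.counts.shape[0] != len(labels):
        raise ValidationError("label names must match matrix dimension")
    flags: list = []
    per_class = {}
    for c, lab in enumerate(labels):
        tp, fp, fn, tn = one_vs_rest_tallies(cm, c)
        pre = _safe_div(tp, tp + fp, flags, lab, "Pre")
        sen = _safe_div(tp, tp + fn, flags, lab, "Sen")
        per_class[lab] = {
            "Acc": (tp + tn) / cm.total,
            "Pre": pre,
            "Sen": sen,
            "Spe": _safe_div(tn, tn + fp, flags, lab, "Spe"),
            "F1": _safe_div(2 * pre * sen, pre + sen, flags, lab, "F1"),
        }
    overall = float(np.trace(cm.counts) / cm.total)
    return MetricsReport(per_class, overall, flags, cm)
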