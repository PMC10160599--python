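"""Binary confusion matrix, classification report, ROC curve and AUC.

Per-class metrics follow the standard definitions: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2*precision*recall/(precision+recall); accuracy is
(TP+TN)/total; macro averages weight classes equally, weighted averages by
support. Zero-denominator cells are reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionMatrix:
    """2x2 counts, rows = true class (0, 1), columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (2, 2) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")
        self.counts = counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, c: int) -> int:
        return int(self.counts[c, c])

    def fn(self, c: int) -> int:
        return int(self.counts[c].sum() - self.counts[c, c])

    def fp(self, c: int) -> int:
        return int(self.counts[:, c].sum() - self.counts[c, c])

    def tn(self, c: int) -> int:
        return self.total - self.tp(c) - self.fn(c) - self.fp(c)

    def support(self, c: int) -> int:
        return int(self.counts[c].sum())


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact integer tabulation of true vs predicted binary labels."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("cannot tabulate empty label vectors")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float, flags: list, what: str):
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


@dataclass
class ClassificationReport:
    per_class: dict                 # class -> {precision, recall, f1, support}
    accuracy: float
    macro_avg: dict
    weighted_avg: dict
    zero_division_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {str(c): dict(v) for c, v in self.per_class.items()}
        out["accuracy"] = self.accuracy
        out["macro avg"] = dict(self.macro_avg)
        out["weighted avg"] = dict(self.weighted_avg)
        if self.zero_division_flags:
            out["zero_division_flags"] = list(self.zero_division_flags)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def report(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class precision/recall/F1/support plus accuracy and averages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list = []
    per_class = {}
    for c in (0, 1):
        precision = _safe_div(cm.tp(c), cm.tp(c) + cm.fp(c), flags, f"precision[{c}]")
        recall = _safe_div(cm.tp(c), cm.tp(c) + cm.fn(c), flags, f"recall[{c}]")
        f1 = _safe_div(2 * recall * precision, recall + precision, flags, f"f1[{c}]")
        per_class[c] = {
            "precision": precision, "recall": recall, "f1": f1,
            "support": cm.support(c),
        }
    accuracy = (cm.counts[0, 0] + cm.counts[1, 1]) / cm.total
    macro = {
        key: float(np.mean([per_class[c][key] for c in (0, 1)]))
        for key in ("precision", "recall", "f1")
    }
    weighted = {
        key: float(sum(per_class[c][key] * per_class[c]["support"] for c in (0, 1))
                   / cm.total)
        for key in ("precision", "recall", "f1")
    }
    macro["support"] = weighted["support"] = cm.total
    return ClassificationReport(
        per_class=per_class, accuracy=float(accuracy),
        macro_avg=macro, weighted_avg=weighted, zero_division_flags=flags,
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray           # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(y_true, scores) -> ROCCurve:
    """Threshold sweep over unique scores; AUC by the trapezoidal rule.

    Equal scores are grouped into a single step.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
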