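"""Confusion matrices, per-class metrics and k-fold aggregation.

Conventions (fixed because they are the only ones consistent with the
reference tables this mirrors): rows of the confusion matrix are the true
class, columns the predicted class, so precision_k reads down column k and
recall_k across row k.  Specificity uses one-vs-rest collapsing.  Display
rounding is half-up to 1 decimal for percentages and 4 decimals for
fractions; internal values are never rounded.  A zero denominator yields a
metric of 0 with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .eeg_core import ParameterError

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "per_class_metrics", "overall_accuracy", "kfold_report",
           "format_percent"]

log = logging.getLogger(__name__)


def format_percent(x: float) -> str:
    """Half-up rounding of a fraction to one-decimal percent text.

    The value is first snapped to 6 decimals so binary float noise (e.g.
    88.85 stored as 88.84999…) cannot flip a half-up boundary.
    """
    return str(Decimal(f"{x * 100:.6f}").quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray              # (K, K), rows = true, cols = predicted
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.class_names)
        if self.counts.shape != (K, K):
            raise ParameterError("counts must be K x K for K class names")
        if (self.counts < 0).any():
            raise ParameterError("counts must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        lines = ["\t" + "\t".join(self.class_names)]
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + "\t" + "\t".join(str(v) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ConfusionMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        names = tuple(lines[0].split("\t")[1:])
        rows = [[int(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
        return cls(np.array(rows), names)


@dataclass
class MetricsReport:
    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_specificity(self) -> float:
        return float(self.specificity.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_json(self) -> str:
        return json.dumps({
            "classes": list(self.class_names),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "specificity": self.specificity.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall,
                      "specificity": self.macro_specificity,
                      "f1": self.macro_f1},
        }, indent=2)


def confusion_matrix(y_true, y_pred, class_names) -> ConfusionMatrix:
    """counts[i, j] = number of epochs with true class i predicted as j."""
    if isinstance(class_names, int):
        class_names = tuple(str(k) for k in range(class_names))
    class_names = tuple(class_names)
    K = len(class_names)
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= K):
        raise ParameterError(f"class index out of range [0, {K})")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("zero denominator for %s; reporting 0", what)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision, recall, specificity and F1 plus overall accuracy."""
    C = cm.counts.astype(float)
    K = cm.K
    total = C.sum()
    prec = np.zeros(K)
    rec = np.zeros(K)
    spec = np.zeros(K)
    f1 = np.zeros(K)
    for k in range(K):
        tp = C[k, k]
        col = C[:, k].sum()
        row = C[k, :].sum()
        fp = col - tp
        tn = total - row - col + tp
        prec[k] = _safe_div(tp, col, f"precision[{cm.class_names[k]}]")
        rec[k] = _safe_div(tp, row, f"recall[{cm.class_names[k]}]")
        spec[k] = _safe_div(tn, tn + fp, f"specificity[{cm.class_names[k]}]")
        f1[k] = _safe_div(2 * prec[k] * rec[k], prec[k] + rec[k],
                          f"f1[{cm.class_names[k]}]")
    acc = _safe_div(np.trace(C), total, "accuracy")
    return MetricsReport(cm.class_names, prec, rec, spec, f1, acc)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total."""
    if cm.total == 0:
        raise ParameterError("cannot compute accuracy of an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def kfold_report(fold_metrics: list[MetricsReport],
                 variance: str = "sample") -> dict[str, dict[str, float]]:
    """Mean and variance of each summary metric across folds.

    ``variance`` selects the divisor: ``"sample"`` (n−1, default) or
    ``"population"`` (n).
    """
    if len(fold_metrics) < 2:
        raise ParameterError("k-fold aggregation needs at least 2 folds")
    if variance not in ("sample", "population"):
        raise ParameterError("variance must be 'sample' or 'population'")
    ddof = 1 if variance == "sample" else 0
    series = {
        "accuracy": np.array([m.accuracy for m in fold_metrics]),
        "precision": np.array([m.macro_precision for m in fold_metrics]),
        "specificity": np.array([m.macro_specificity for m in fold_metrics]),
        "recall": np.array([m.macro_recall for m in fold_metrics]),
        "f1": np.array([m.macro_f1 for m in fold_metrics]),
    }
    return {name: {"mean": float(v.mean()), "variance": float(v.var(ddof=ddof))}
            for name, v in series.items()}
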