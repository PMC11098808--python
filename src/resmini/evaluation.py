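"""Confusion matrices, accuracy, macro recall/precision, comparison reports.

Conventions: confusion-matrix rows are true classes, columns predicted;
recall of class c is ``diag_c / row_sum_c``, precision ``diag_c /
col_sum_c`` (0 when the column is empty); macro metrics are unweighted
means over classes.  Argmax ties resolve to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import engine


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts: rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(self.class_names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    per_class_recall: tuple[float, ...]
    per_class_precision: tuple[float, ...]
    macro_recall: float
    macro_precision: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_recall": list(self.per_class_recall),
            "per_class_precision": list(self.per_class_precision),
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
        }


def confusion_matrix(true_labels: Sequence[int], predicted_labels: Sequence[int],
                     num_classes: int,
                     class_names: Sequence[str] | None = None) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label vectors differ in length")
    for v in (true_labels, predicted_labels):
        if v.size and (v.min() < 0 or v.max() >= num_classes):
            raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = _sk_confusion(true_labels, predicted_labels,
                           labels=np.arange(num_classes))
    names = tuple(class_names) if class_names is not None else tuple(
        f"class{i}" for i in range(num_classes))
    return ConfusionMatrix(counts=counts, class_names=names)


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    return Metrics(
        accuracy=float(diag.sum() / total),
        per_class_recall=tuple(float(r) for r in recall),
        per_class_precision=tuple(float(p) for p in precision),
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
    )


def evaluate(model: engine.Network, test_set: tuple[np.ndarray, np.ndarray],
             class_names: Sequence[str] | None = None, batch_size: int = 64,
             ) -> tuple[ConfusionMatrix, Metrics]:
    """Predict a test set and derive its confusion matrix and metrics."""
    x, y = test_set
    if len(x) == 0:
        raise ValueError("test set is empty")
    preds = np.concatenate([
        model.predict(x[i:i + batch_size]) for i in range(0, len(x), batch_size)])
    cm = confusion_matrix(y, preds, model.num_classes, class_names)
    return cm, metrics_from_confusion(cm)


def parameter_ratio_percent(numerator_total: int, denominator_total: int) -> float:
    """Parameter-economy ratio as a percentage, rounded to 2 d.p."""
    if denominator_total <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator_total / denominator_total, 2)


def percentage_point_gain(accuracy_before: float, accuracy_after: float) -> float:
    """Accuracy improvement in percentage points (e.g. 0.741 -> 0.967 is 22.6)."""
    return round(100.0 * (accuracy_after - accuracy_before), 1)


def comparison_report(names: Sequence[str], totals: Sequence[int],
                      accuracies: Sequence[float | None]) -> dict:
    """Accuracy/parameter table plus all pairwise parameter ratios.

    Ratios are percentages to 2 d.p.: with the published totals 98,907 /
    196,595 / 11,181,379 the first model's parameters are 50.31% and 0.88%
    of the other two.
    """
    if not len(names) == len(totals) == len(accuracies):
        raise ValueError("names, totals and accuracies must align")
    models = [{"name": n, "total_parameters": int(t), "accuracy": a}
              for n, t, a in zip(names, totals, accuracies)]
    ratios = {
        f"{a}/{b}": parameter_ratio_percent(ta, tb)
        for a, ta in zip(names, totals)
        for b, tb in zip(names, totals)
    }
    return {"models": models, "parameter_ratio_percent": ratios}


def comparison_report_text(report: dict) -> str:
    lines = [f"{'model':<12} {'accuracy':>9} {'parameters':>12}"]
    for m in report["models"]:
        acc = "-" if m["accuracy"] is None else f"{m['accuracy']:.3f}"
        lines.append(f"{m['name']:<12} {acc:>9} {m['total_parameters']:>12,}")
    lines.append("parameter ratios (%):")
    for pair, pct in report["parameter_ratio_percent"].items():
        lines.append(f"  {pair:<25} {pct:>8.2f}")
    return "\n".join(lines)
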