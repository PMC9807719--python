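"""Confusion-matrix construction and multi-class evaluation metrics.

Rows of the confusion matrix are true classes, columns are predictions.
Per-class precision, recall, F1 and specificity come from the one-vs-rest
reduction of the matrix; macro values are unweighted means over classes;
overall accuracy is trace/total.  All metric values are percentages in
[0, 100].

Zero-denominator convention: a per-class metric whose denominator is zero
is reported as 0 and the class is listed in ``EvalReport.degenerate`` so
the condition is never silent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "one_vs_rest",
    "class_metrics",
    "report",
]

_METRIC_NAMES = ("precision", "recall", "f1", "specificity")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count table; ``counts[i][j]`` = samples with true i, predicted j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.class_names) != c.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, stream: IO[str]) -> None:
        writer = csv.writer(stream)
        writer.writerow(["true\\pred", *self.class_names])
        for name, row in zip(self.class_names, self.counts):
            writer.writerow([name, *row.tolist()])

    @classmethod
    def from_csv(cls, stream: IO[str]) -> "ConfusionMatrix":
        rows = list(csv.reader(stream))
        names = tuple(rows[0][1:])
        counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=np.int64)
        return cls(counts=counts, class_names=names)


def confusion_matrix(true_labels, predicted_labels, n_classes: int,
                     class_names: Sequence[str] | None = None) -> ConfusionMatrix:
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    for arr, what in ((y, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{what} labels out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    names = tuple(class_names) if class_names is not None else tuple(
        f"class{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=names)


def one_vs_rest(cm: ConfusionMatrix, class_index: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for one class; the four always sum to the total."""
    if not 0 <= class_index < cm.n_classes:
        raise IndexError(f"class_index {class_index} out of range")
    c = cm.counts
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum()) - tp
    fn = int(c[class_index, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _pct(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def class_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Precision, recall, F1, specificity and accuracy (percent) from
    one-vs-rest counts.  Accuracy here is the binary (TP+TN)/total form;
    for the multi-class overall accuracy use trace/total via :func:`report`.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    precision, p_deg = _pct(tp, tp + fp)
    recall, r_deg = _pct(tp, tp + fn)
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
        f_deg = False
    else:
        f1, f_deg = 0.0, True
    specificity, s_deg = _pct(tn, tn + fp)
    accuracy, _ = _pct(tp + tn, tp + fp + fn + tn)
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "specificity": specificity, "accuracy": accuracy,
        "degenerate": bool(p_deg or r_deg or f_deg or s_deg),
    }


@dataclass(frozen=True)
class EvalReport:
    """Overall accuracy (%), loss, per-class and macro metrics (%)."""

    accuracy: float
    loss: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    support: dict[str, int]
    degenerate: tuple[str, ...] = ()

    def to_json(self) -> str:
        doc = {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "per_class": self.per_class,
            "macro": self.macro,
            "support": self.support,
            "degenerate": list(self.degenerate),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        doc = json.loads(text)
        return cls(accuracy=doc["accuracy"], loss=doc["loss"],
                   per_class=doc["per_class"], macro=doc["macro"],
                   support={k: int(v) for k, v in doc["support"].items()},
                   degenerate=tuple(doc.get("degenerate", ())))


def report(cm: ConfusionMatrix, loss: float = float("nan")) -> EvalReport:
    """Full evaluation report from a confusion matrix.

    Overall accuracy is trace/total; macro metrics are unweighted means of
    the per-class one-vs-rest values.
    """
    if cm.total == 0:
        raise ValueError("cannot report on an empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    degenerate: list[str] = []
    for i, name in enumerate(cm.class_names):
        m = class_metrics(*one_vs_rest(cm, i))
        if m.pop("degenerate"):
            degenerate.append(name)
        m.pop("accuracy")  # per-class binary accuracy is not reported
        per_class[name] = m
    macro = {k: float(np.mean([per_class[n][k] for n in cm.class_names]))
             for k in _METRIC_NAMES}
    support = {name: int(cm.counts[i].sum()) for i, name in enumerate(cm.class_names)}
    accuracy = 100.0 * float(np.trace(cm.counts)) / cm.total
    return EvalReport(accuracy=accuracy, loss=float(loss), per_class=per_class,
                      macro=macro, support=support, degenerate=tuple(degenerate))
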