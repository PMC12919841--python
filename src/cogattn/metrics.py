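"""Classification metrics for two-class and multi-class evaluation.

Two-class metrics use the standard confusion-matrix formulas (accuracy,
precision, sensitivity/recall, specificity, F1), expressed as percentages.
Multi-class metrics are macro-averaged one-vs-rest: each class is treated in
turn as the positive class, the per-class metric is computed from its
one-vs-rest TP/TN/FP/FN counts, and the unweighted mean over classes is
reported.  Macro accuracy therefore averages per-class one-vs-rest
accuracies; the plain ``trace/total`` accuracy is available separately as
:func:`overall_accuracy`.

Undefined ratios (zero denominators) are reported as ``None`` — an explicit
marker, never a silent zero — and excluded from macro means with a warning.

Fold aggregation uses the arithmetic mean and the *population* standard
deviation (divisor N); with that divisor the printed per-fold accuracies of
a 5-fold run reproduce their printed mean and spread exactly.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ConfusionMatrix", "MetricReport", "FoldSummary",
    "binary_metrics", "macro_metrics", "overall_accuracy",
    "fold_mean", "fold_std", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (3.125 -> 3.13 at 2 digits)."""
    if x is None:
        return None
    factor = 10 ** ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class MetricReport:
    """Five headline metrics as percentages in [0, 100]; None marks undefined."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> "MetricReport":
        return MetricReport(*[round_half_up(getattr(self, f.name), ndigits)
                              for f in fields(self)])

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class."""

    def __init__(self, counts, class_labels=None):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] < 2:
            raise ValueError("confusion matrix needs at least 2 classes")
        if np.any(counts < 0) or not np.all(counts == np.round(counts)):
            raise ValueError("confusion matrix entries must be nonnegative integers")
        self.counts = counts.astype(np.int64)
        self.class_labels = (list(class_labels) if class_labels is not None
                             else list(range(counts.shape[0])))
        if len(self.class_labels) != counts.shape[0]:
            raise ValueError("class_labels length must match matrix size")

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes=None, class_labels=None):
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must align")
        k = n_classes if n_classes is not None else int(max(y_true.max(), y_pred.max())) + 1
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts, class_labels)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, index: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``index`` as the positive class."""
        tp = int(self.counts[index, index])
        fn = int(self.counts[index].sum()) - tp
        fp = int(self.counts[:, index].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["true\\pred"] + [str(c) for c in self.class_labels])
        for label, row in zip(self.class_labels, self.counts):
            w.writerow([str(label)] + [int(v) for v in row])
        return buf.getvalue()

    def to_dict(self) -> dict:
        return {"class_labels": self.class_labels,
                "counts": self.counts.tolist()}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _f1(precision, sensitivity):
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        return None
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def binary_metrics(cm: ConfusionMatrix, positive: int = 0) -> MetricReport:
    """Two-class metrics with ``positive`` as the designated positive class."""
    if cm.n_classes != 2:
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    tp, tn, fp, fn = cm.one_vs_rest(positive)
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    report = MetricReport(
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(tn, tn + fp),
        f1=_f1(precision, sensitivity),
    )
    undefined = [k for k, v in report.to_dict().items() if v is None]
    if undefined:
        warnings.warn("undefined metric(s) reported as None: "
                      + ", ".join(undefined))
    return report


def macro_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Macro-averaged one-vs-rest metrics over all classes."""
    per_class = {"accuracy": [], "precision": [], "sensitivity": [],
                 "specificity": [], "f1": []}
    flagged = []
    for i in range(cm.n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        vals = {
            "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
            "precision": _ratio(tp, tp + fp),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
        }
        vals["f1"] = _f1(vals["precision"], vals["sensitivity"])
        for k, v in vals.items():
            if v is None:
                flagged.append((cm.class_labels[i], k))
            else:
                per_class[k].append(v)
    if flagged:
        warnings.warn("undefined per-class metric(s) excluded from macro mean: "
                      + ", ".join(f"{c}:{m}" for c, m in flagged))
    means = {k: (float(np.mean(v)) if v else None) for k, v in per_class.items()}
    return MetricReport(**means)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Plain accuracy, correct predictions over total (percent)."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def fold_mean(values) -> float:
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("fold_mean of an empty list")
    return float(values.mean())


def fold_std(values) -> float:
    """Population standard deviation (divisor N) of per-fold values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("fold_std of an empty list")
    return float(values.std(ddof=0))


@dataclass
class FoldSummary:
    """Per-fold metric reports with their mean and population spread."""

    per_fold: list
    metric: str = "accuracy"

    @property
    def values(self) -> list:
        return [getattr(r, self.metric) for r in self.per_fold]

    @property
    def mean(self) -> float:
        return fold_mean(self.values)

    @property
    def std(self) -> float:
        return fold_std(self.values)

    @property
    def mean_report(self) -> MetricReport:
        cols = {}
        for f in fields(MetricReport):
            vals = [getattr(r, f.name) for r in self.per_fold]
            cols[f.name] = fold_mean([v for v in vals if v is not None]) \
                if any(v is not None for v in vals) else None
        return MetricReport(**cols)

    def to_dict(self) -> dict:
        return {"per_fold": [r.to_dict() for r in self.per_fold],
                "metric": self.metric,
                "mean": self.mean, "std": self.std}
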