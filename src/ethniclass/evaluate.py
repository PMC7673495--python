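"""Evaluation metrics for multiclass and binary ethnicity classification.

Per-class metrics are one-vs-rest: for each class the multiclass
confusion matrix is collapsed to TP/FP/FN/TN and sensitivity,
specificity, PPV, NPV, F1 and accuracy are computed from the collapse.
Undefined ratios (zero denominators) propagate as NaN, never as 0.
Overall rows are support-weighted averages of the per-class values —
including accuracy, which is why the overall accuracy exceeds the
micro accuracy (trace/total) on imbalanced data. Threshold-sweep
summaries (AUC-ROC and average PPV, i.e. average precision) are
computed from continuous class scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.metrics import confusion_matrix as _sk_confusion

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy")
CURVE_METRIC_NAMES = ("auc_roc", "average_ppv")


@dataclass
class ConfusionMatrix:
    """Truth-rows x predicted-columns count grid over an ordered label list."""

    labels: list[str]
    counts: np.ndarray  # shape (n_labels, n_labels), dtype int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("confusion grid shape does not match label list")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def supports(self) -> dict[str, int]:
        """True-record count per class (row totals)."""
        row = self.counts.sum(axis=1)
        return {lab: int(row[i]) for i, lab in enumerate(self.labels)}


@dataclass
class MetricsReport:
    """Per-class and support-weighted overall metrics."""

    labels: list[str]
    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]
    supports: dict[str, int]
    confusion: Optional[ConfusionMatrix] = None
    extra: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form: every metric rounded (reports print at 2 d.p.)."""
        rnd = lambda d: {k: (round(v, ndigits) if v == v else float("nan")) for k, v in d.items()}
        return {
            "per_class": {lab: rnd(m) for lab, m in self.per_class.items()},
            "overall": rnd(self.overall),
            "supports": self.supports,
        }


def confusion(truth: Sequence, predicted: Sequence, labels: Sequence[str]) -> ConfusionMatrix:
    """Count grid with cell (i, j) = records of true class i predicted j."""
    truth = list(truth)
    predicted = list(predicted)
    if not truth or len(truth) != len(predicted):
        raise ValueError("truth and predicted must be equal-length and non-empty")
    known = set(labels)
    for seq, what in ((truth, "truth"), (predicted, "predicted")):
        bad = set(seq) - known
        if bad:
            raise ValueError(f"{what} contains labels outside the label order: {sorted(bad)}")
    counts = _sk_confusion(truth, predicted, labels=list(labels))
    return ConfusionMatrix(list(labels), counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float]:
    """One-vs-rest sensitivity/specificity/PPV/NPV/F1/accuracy for *cls*."""
    if cls not in cm.labels:
        raise ValueError(f"class {cls!r} not in label order")
    i = cm.labels.index(cls)
    counts = cm.counts
    tp = float(counts[i, i])
    fn = float(counts[i, :].sum() - tp)
    fp = float(counts[:, i].sum() - tp)
    tn = float(counts.sum() - tp - fn - fp)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    if math.isnan(sens) or math.isnan(ppv) or (sens + ppv) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "accuracy": acc,
    }


def overall(per_class: dict[str, dict[str, float]], supports: dict[str, int]) -> dict[str, float]:
    """Support-weighted average of each per-class metric.

    Classes whose metric is undefined (NaN) are excluded from that
    metric's average together with their support.
    """
    out: dict[str, float] = {}
    metric_names = set()
    for m in per_class.values():
        metric_names.update(m)
    for name in sorted(metric_names):
        num = den = 0.0
        for lab, metrics in per_class.items():
            v = metrics.get(name, float("nan"))
            if v == v:  # not NaN
                w = supports.get(lab, 0)
                num += w * v
                den += w
        out[name] = num / den if den > 0 else float("nan")
    return out


def threshold_curves(scores: Sequence[float], truth: Sequence[int]) -> tuple[float, float]:
    """AUC-ROC and average PPV (average precision) from continuous scores.

    AUC-ROC is the probability that a random positive outscores a random
    negative (ties count 1/2). Average PPV is precision averaged over the
    recall steps of the precision-recall curve. Single-class truth makes
    both undefined (NaN).
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.min() == truth.max():
        return float("nan"), float("nan")
    return float(roc_auc_score(truth, scores)), float(average_precision_score(truth, scores))


def report_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    per_class = {lab: class_metrics(cm, lab) for lab in cm.labels}
    supports = cm.supports()
    return MetricsReport(
        labels=list(cm.labels),
        per_class=per_class,
        overall=overall(per_class, supports),
        supports=supports,
        confusion=cm,
    )


def multiclass_report(
    truth: Sequence,
    predicted: Sequence,
    labels: Sequence[str],
    scores: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Full multiclass report; *scores* (records x labels) adds per-class
    one-vs-rest AUC-ROC and average PPV."""
    cm = confusion(truth, predicted, labels)
    report = report_from_confusion(cm)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        truth_arr = np.asarray(list(truth))
        for j, lab in enumerate(labels):
            auc, ap = threshold_curves(scores[:, j], (truth_arr == lab).astype(int))
            report.per_class[lab]["auc_roc"] = auc
            report.per_class[lab]["average_ppv"] = ap
        report.overall = overall(report.per_class, report.supports)
    return report


def binary_report(
    truth: Sequence[int],
    predicted: Sequence[int],
    scores: Optional[Sequence[float]] = None,
    positive_name: str = "positive",
) -> MetricsReport:
    """Report for a binary target; metrics are those of the positive class."""
    labels = ["negative", positive_name]
    as_name = lambda seq: [labels[int(v)] for v in seq]
    cm = confusion(as_name(truth), as_name(predicted), labels)
    metrics = class_metrics(cm, positive_name)
    if scores is not None:
        auc, ap = threshold_curves(scores, truth)
        metrics["auc_roc"] = auc
        metrics["average_ppv"] = ap
    supports = cm.supports()
    return MetricsReport(
        labels=labels,
        per_class={positive_name: metrics},
        overall=dict(metrics),
        supports={positive_name: supports[positive_name]},
        confusion=cm,
    )
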