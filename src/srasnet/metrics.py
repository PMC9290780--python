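"""Per-class and overall evaluation for the 24-way chromosome classifier.

For each class *i* the one-vs-rest counts are taken from the confusion
matrix (rows = true class, columns = predicted):

    TP_i = cm[i, i]          FN_i = row_i - TP_i
    FP_i = col_i - TP_i      TN_i = total - TP_i - FP_i - FN_i

and the reported quantities are

    Acc_i  = (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i)
    P_i    = TP_i / (TP_i + FP_i)
    R_i    = TP_i / (TP_i + FN_i)
    F1_i   = 2 P_i R_i / (P_i + R_i)

Overall accuracy comes in two flavours: the one-vs-rest aggregate
sum_i (TP_i + TN_i) / sum_i (TP_i + TN_i + FP_i + FN_i), which equals the
mean of the per-class Acc_i and is inflated by true negatives, and the
standard top-1 accuracy trace/total.  Both are always reported; the
headline figure is the standard one.  Percentages are printed with two
decimals (round-half-even).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ClassCounts", "MetricsReport", "confusion_matrix",
           "per_class_metrics", "overall_accuracy", "f1_from_pr",
           "f1_from_pr_counts", "evaluate_predictions"]

logger = logging.getLogger(__name__)

N_CLASSES = 24


@dataclass(frozen=True)
class ClassCounts:
    TP: int
    FP: int
    TN: int
    FN: int


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists differ in length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes or
                        y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels outside 0-{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _pct(x: float) -> float:
    """Percentage with two decimals, round-half-even."""
    return float(np.round(100.0 * x, 2))


def f1_from_pr(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall given in percent, reported in
    percent with two decimals (0 when both are 0)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return float(np.round(2 * precision_pct * recall_pct /
                          (precision_pct + recall_pct), 2))


def f1_from_pr_counts(precision_pct: float, recall_pct: float,
                      max_tp: int = 2000) -> float:
    """F1 (percent, 2 d.p.) from precision/recall printed at two decimals.

    Published tables round P and R before printing but compute F1 from the
    underlying integer counts, so the harmonic mean of the printed values
    can be off in the last digit.  This recovers the smallest integer
    (TP, FP, FN) whose exact ratios round to the printed percentages and
    returns 2*TP / (2*TP + FP + FN) from those counts.
    """
    for tp in range(1, max_tp + 1):
        fp = _match_count(tp, precision_pct)
        fn = _match_count(tp, recall_pct)
        if fp is not None and fn is not None:
            return float(np.round(100.0 * 2 * tp / (2 * tp + fp + fn), 2))
    raise ValueError("no integer counts reproduce the printed values")


def _match_count(tp: int, pct: float) -> int | None:
    """Smallest k >= 0 with round(100*tp/(tp+k), 2) == pct, else None."""
    if pct <= 0:
        return None
    k_approx = tp * (100.0 / pct - 1.0)
    for k in sorted({int(np.floor(k_approx)), int(np.ceil(k_approx))}):
        if k >= 0 and np.round(100.0 * tp / (tp + k), 2) == np.round(pct, 2):
            return k
    return None


def per_class_metrics(cm: np.ndarray) -> tuple[list[ClassCounts], dict]:
    """One-vs-rest counts and Acc/P/R/F1 (percent) for every class."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    counts, acc, prec, rec, f1 = [], [], [], [], []
    for i in range(cm.shape[0]):
        tp = int(cm[i, i])
        fn = int(cm[i].sum()) - tp
        fp = int(cm[:, i].sum()) - tp
        tn = total - tp - fn - fp
        counts.append(ClassCounts(tp, fp, tn, fn))
        acc.append(_pct((tp + tn) / total) if total else 0.0)
        if tp + fp == 0:
            logger.warning("class %d: no predictions, precision set to 0", i)
            p = 0.0
        else:
            p = tp / (tp + fp)
        if tp + fn == 0:
            logger.warning("class %d: no support, recall set to 0", i)
            r = 0.0
        else:
            r = tp / (tp + fn)
        prec.append(_pct(p))
        rec.append(_pct(r))
        f1.append(f1_from_pr(_pct(p), _pct(r)))
    return counts, {"acc": acc, "precision": prec, "recall": rec, "f1": f1}


def overall_accuracy(cm: np.ndarray) -> tuple[float, float]:
    """(one-vs-rest aggregate accuracy, standard top-1 accuracy), percent.

    The first equals the mean of the per-class one-vs-rest accuracies;
    the second is trace/total.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    tp = np.trace(cm)
    # per class i: TP_i + TN_i = total - FP_i - FN_i; summed over classes
    fp_fn = 2 * (total - tp)  # each error is one FP and one FN
    acc_ovr = (k * total - fp_fn) / (k * total)
    acc_std = tp / total
    return _pct(float(acc_ovr)), _pct(float(acc_std))


@dataclass
class MetricsReport:
    confusion: np.ndarray
    counts: list[ClassCounts]
    per_class: dict
    overall_ovr: float
    overall_standard: float
    labels: list[int] = field(default_factory=lambda: list(range(N_CLASSES)))

    def to_dict(self) -> dict:
        return {
            "overall_accuracy_standard": self.overall_standard,
            "overall_accuracy_one_vs_rest": self.overall_ovr,
            "per_class": {
                str(lbl): {
                    "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
                    "acc": self.per_class["acc"][i],
                    "precision": self.per_class["precision"][i],
                    "recall": self.per_class["recall"][i],
                    "f1": self.per_class["f1"][i],
                }
                for i, (lbl, c) in enumerate(zip(self.labels, self.counts))
            },
            "confusion_matrix": self.confusion.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_text(self) -> str:
        names = {0: "Y", 23: "X"}
        lines = [f"{'Class':>5} {'Acc.(%)':>8} {'Prec.(%)':>9} "
                 f"{'Recall(%)':>10} {'F1(%)':>8}"]
        for i, lbl in enumerate(self.labels):
            name = names.get(lbl, str(lbl))
            lines.append(
                f"{name:>5} {self.per_class['acc'][i]:>8.2f} "
                f"{self.per_class['precision'][i]:>9.2f} "
                f"{self.per_class['recall'][i]:>10.2f} "
                f"{self.per_class['f1'][i]:>8.2f}")
        lines.append(f"Overall accuracy (top-1): {self.overall_standard:.2f}%"
                     f"   (one-vs-rest: {self.overall_ovr:.2f}%)")
        return "\n".join(lines)


def evaluate_predictions(y_true, y_pred,
                         n_classes: int = N_CLASSES) -> MetricsReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    counts, per_cls = per_class_metrics(cm)
    ovr, std = overall_accuracy(cm)
    return MetricsReport(cm, counts, per_cls, ovr, std,
                         labels=list(range(n_classes)))
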