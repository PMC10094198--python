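"""Multi-label evaluation: per-class precision, recall, F1, accuracy, AUC.

Definitions: precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2·precision·recall/(precision+recall); the macro F1 is the unweighted
arithmetic mean of per-class F1 scores.  AUC is the one-vs-rest area under
the ROC curve, computed as the pairwise ranking statistic
P(score_pos > score_neg) + 0.5·P(tie).  Whenever a ratio's denominator is
zero the value is reported as 0 (affects very rare classes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion_counts", "precision_recall",
    "f1_score", "macro_f1", "auc", "compute_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class binary confusion counts over a set of evaluated records."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


def confusion_counts(predicted: np.ndarray, targets: np.ndarray
                     ) -> list[ConfusionCounts]:
    """Tally binary confusion counts per class from (N, C) indicator arrays."""
    pred = np.asarray(predicted, dtype=bool)
    targ = np.asarray(targets, dtype=bool)
    if pred.shape != targ.shape:
        raise ValueError("prediction and target shapes differ")
    out = []
    for c in range(pred.shape[1]):
        p, t = pred[:, c], targ[:, c]
        out.append(ConfusionCounts(
            tp=int((p & t).sum()), fp=int((p & ~t).sum()),
            fn=int((~p & t).sum()), tn=int((~p & ~t).sum())))
    return out


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall), each 0 when its denominator is 0."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = precision + recall
    return 2.0 * precision * recall / denom if denom else 0.0


def macro_f1(per_class_f1) -> float:
    """Unweighted arithmetic mean of per-class F1 scores."""
    values = list(per_class_f1)
    if not values:
        raise ValueError("macro F1 of an empty class list is undefined")
    return float(np.mean(values))


def auc(scores: np.ndarray, targets: np.ndarray) -> float:
    """One-vs-rest ROC area via the rank statistic (ties counted as 1/2).

    Raises if the class has no positive or no negative record, in which case
    the ROC curve is undefined.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(targets, dtype=bool)
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(s)  # average ranks handle ties exactly
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged evaluation results.

    ``per_class`` maps class name -> dict with keys auc, accuracy, precision,
    recall, f1 (auc may be NaN when undefined for that class).
    """

    per_class: dict[str, dict[str, float]]
    macro_f1: float
    macro_auc: float
    macro_accuracy: float
    macro_precision: float
    macro_recall: float

    _COLUMNS = ("auc", "accuracy", "precision", "recall", "f1")

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the usual report layout, with a final AVG row."""
        rows = {name: [vals[c] for c in self._COLUMNS]
                for name, vals in self.per_class.items()}
        rows["AVG"] = [self.macro_auc, self.macro_accuracy, self.macro_precision,
                       self.macro_recall, self.macro_f1]
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["AUC", "Accuracy", "Precision", "Recall", "F1"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="Type")

    def to_json(self, path=None) -> str:
        payload = {
            "per_class": self.per_class,
            "macro": {"f1": self.macro_f1, "auc": self.macro_auc,
                      "accuracy": self.macro_accuracy,
                      "precision": self.macro_precision,
                      "recall": self.macro_recall},
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_report(scores: np.ndarray, targets: np.ndarray,
                   class_names: list[str], threshold: float = 0.5
                   ) -> MetricsReport:
    """Full multi-label report from raw per-class scores.

    Count-based metrics binarize at ``threshold``; AUC uses the raw scores.
    Classes whose AUC is undefined (single-class targets) are reported as
    NaN and excluded from the macro AUC with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=bool)
    if scores.shape != targets.shape:
        raise ValueError("scores and targets shapes differ")
    if scores.shape[1] != len(class_names):
        raise ValueError("class_names length does not match score columns")
    counts = confusion_counts(scores >= threshold, targets)
    per_class: dict[str, dict[str, float]] = {}
    aucs = []
    for name, cc, col in zip(class_names, counts, range(scores.shape[1])):
        precision, recall = precision_recall(cc)
        try:
            a = auc(scores[:, col], targets[:, col])
            aucs.append(a)
        except ValueError:
            warnings.warn(f"AUC undefined for class {name!r}; excluded from macro")
            a = float("nan")
        per_class[name] = {
            "auc": a, "accuracy": cc.accuracy, "precision": precision,
            "recall": recall, "f1": f1_score(precision, recall),
        }
    return MetricsReport(
        per_class=per_class,
        macro_f1=macro_f1([v["f1"] for v in per_class.values()]),
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
        macro_accuracy=float(np.mean([v["accuracy"] for v in per_class.values()])),
        macro_precision=float(np.mean([v["precision"] for v in per_class.values()])),
        macro_recall=float(np.mean([v["recall"] for v in per_class.values()])),
    )
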