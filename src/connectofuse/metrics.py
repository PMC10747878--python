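"""Binary-classifier evaluation: confusion counts, ACC/SEN/PRE/F1, ROC/AUC.

The positive class throughout the package is the case group (label 1), which
fixes the semantics of sensitivity and precision.  Ratios with a zero
denominator are reported as 0 together with an explicit flag, so metric
reports stay machine-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["MetricsReport", "confusion_metrics", "roc_auc", "evaluate_predictions"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    pre: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    undefined: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "acc": self.acc,
            "sen": self.sen,
            "pre": self.pre,
            "f1": self.f1,
            "auc": self.auc,
            "undefined": self.undefined,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int):
    """ACC, SEN (recall), PRE and F1 from confusion counts.

    Returns ``(acc, sen, pre, f1, undefined)`` where ``undefined`` lists the
    metrics whose denominator was zero (each reported as 0).
    """
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count {name}={c}")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("all counts are zero")
    undefined = []
    acc = (tp + tn) / n
    if tp + fn > 0:
        sen = tp / (tp + fn)
    else:
        sen, _ = 0.0, undefined.append("sen")
    if tp + fp > 0:
        pre = tp / (tp + fp)
    else:
        pre, _ = 0.0, undefined.append("pre")
    if pre + sen > 0:
        f1 = 2 * pre * sen / (pre + sen)
    else:
        f1, _ = 0.0, undefined.append("f1")
    return acc, sen, pre, f1, undefined


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """Trapezoidal area under the ROC curve, plus the curve's points.

    Equals the concordance probability P[score_pos > score_neg] with ties
    counted one half (the rank / Mann-Whitney convention).  Scores are the
    positive-class probabilities.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_predictions(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full metric panel from positive-class scores and true labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc, sen, pre, f1, undefined = confusion_metrics(tp, fp, tn, fn)
    if len(np.unique(labels)) == 2:
        auc, points = roc_auc(scores, labels)
    else:
        auc, points = 0.0, []
        undefined.append("auc")
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sen=sen, pre=pre, f1=f1, auc=auc,
        roc_points=points, undefined=undefined,
    )
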