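"""Confusion-matrix metrics and ROC/AUC.

Accuracy, sensitivity, specificity, PPV and NPV are the standard
confusion ratios reported as percentages; a metric whose denominator is
zero is reported as ``None`` (undefined) rather than silently zeroed.
AUC uses the rank (pairwise-concordance) statistic with ties counted 1/2,
which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_at_threshold",
    "compute_metrics",
    "roc_auc",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    PPV: float | None
    NPV: float | None
    confusion: ConfusionCounts
    AUC: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "PPV": self.PPV,
            "NPV": self.NPV,
            "AUC": self.AUC,
            "confusion": {
                "TP": self.confusion.TP,
                "FP": self.confusion.FP,
                "TN": self.confusion.TN,
                "FN": self.confusion.FN,
            },
        }
        if self.roc_points is not None:
            d["roc_points"] = [list(p) for p in self.roc_points]
        return d


def confusion_at_threshold(
    scores, labels, threshold: float = 0.5
) -> ConfusionCounts:
    """Counts from comparing score >= threshold against binary labels."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else round(100.0 * num / den, 2)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The five confusion ratios as percentages (two-decimal reporting)."""
    return MetricsReport(
        accuracy=_pct(c.TP + c.TN, c.n),
        sensitivity=_pct(c.TP, c.TP + c.FN),
        specificity=_pct(c.TN, c.TN + c.FP),
        PPV=_pct(c.TP, c.TP + c.FP),
        NPV=_pct(c.TN, c.TN + c.FN),
        confusion=c,
    )


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the rank statistic with tie correction, plus ROC points.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    ranks averaged over ties; equivalently the probability that a random
    positive outscores a random negative, ties counting one half.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # ROC points over all score thresholds, descending
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(ss)):
        if ys[i] == 1:
            tp += 1
        else:
            fp += 1
        if i + 1 < len(ss) and ss[i + 1] == ss[i]:
            continue
        points.append((fp / n_neg, tp / n_pos))
    return float(auc), points


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics plus AUC/ROC in one report."""
    c = confusion_at_threshold(scores, labels, threshold)
    report = compute_metrics(c)
    auc, points = roc_auc(scores, labels)
    report.AUC = auc
    report.roc_points = points
    return report
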