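"""ROC curves, AUC, and Youden-optimal operating points.

The ROC curve traces sensitivity against specificity over every decision
threshold of a continuous risk score; classification is "event" when the
score is at or above the threshold.  The trapezoidal area under the curve
equals the Mann-Whitney probability that a random event outscores a random
non-event (ties counted 1/2).  The Youden index J = sensitivity +
specificity - 1 selects the operating threshold; predictive values at that
threshold come from the implied 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stratify import ContingencyTable, predictive_values

__all__ = ["ROCResult", "OperatingPoint", "roc_curve", "auc", "youden", "bootstrap_auc_ci"]


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class ROCResult:
    points: list[OperatingPoint]
    auc: float
    n_events: int
    n_nonevents: int

    def implied_table(self, point: OperatingPoint) -> ContingencyTable:
        return ContingencyTable(
            a=point.tp,
            b=point.fp,
            c=self.n_events - point.tp,
            d=self.n_nonevents - point.fp,
        )


def _validate(scores: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=float)
    ok = ~np.isnan(scores) & ~np.isnan(events)
    scores, events = scores[ok], events[ok].astype(int)
    if set(np.unique(events)) - {0, 1}:
        raise ValueError("events must be coded 0/1")
    if events.min() == events.max():
        raise ValueError("both classes must be present to build a ROC curve")
    return scores, events


def roc_curve(scores: np.ndarray, events: np.ndarray) -> ROCResult:
    """Operating points at every distinct score value, ties grouped.

    The first point (threshold +inf) classifies nothing as an event; each
    subsequent point lowers the threshold to the next distinct score.
    """
    scores, events = _validate(scores, events)
    n_pos = int(events.sum())
    n_neg = events.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s, e = scores[order], events[order]
    points = [OperatingPoint(math.inf, 0.0, 1.0, 0, 0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:
            tp += int(e[j])
            fp += int(1 - e[j])
            j += 1
        points.append(OperatingPoint(float(s[i]), tp / n_pos, (n_neg - fp) / n_neg, tp, fp))
        i = j
    # trapezoid over (FPR, TPR)
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=points, auc=area, n_events=n_pos, n_nonevents=n_neg)


def auc(scores: np.ndarray, events: np.ndarray) -> float:
    """Area under the ROC curve (equals the tie-adjusted Mann-Whitney estimator)."""
    return roc_curve(scores, events).auc


def youden(roc: ROCResult) -> dict:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward the point with higher sensitivity.  PPV and
    NPV at the chosen threshold are computed from the implied 2x2 table.
    """
    if not roc.points:
        raise ValueError("empty ROC curve")
    best = max(roc.points, key=lambda p: (round(p.youden_j, 12), p.sensitivity))
    pv = predictive_values(roc.implied_table(best))
    return {
        "threshold": best.threshold,
        "sensitivity": best.sensitivity,
        "specificity": best.specificity,
        "youden_j": best.youden_j,
        "ppv": pv["ppv"],
        "npv": pv["npv"],
    }


def bootstrap_auc_ci(
    scores: np.ndarray,
    events: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (descriptive convenience only)."""
    scores, events = _validate(scores, events)
    rng = np.random.default_rng(seed)
    n = scores.size
    stats_ = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        e = events[idx]
        if e.min() == e.max():
            continue
        stats_.append(roc_curve(scores[idx], e).auc)
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
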