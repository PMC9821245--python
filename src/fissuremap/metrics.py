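"""Diagnostic test statistics for the fissure classifiers.

Confusion-table measures (sensitivity, specificity, accuracy, likelihood
ratios), ROC analysis, and the exact mid-p McNemar test used to compare
the texture-feature classifier against the high-intensity-zone marker on
paired predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "McNemarResult",
    "confusion",
    "diagnostic_metrics",
    "roc_auc",
    "mcnemar_midp",
    "discordant_counts",
]


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts; positive = outer annular fissure."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Derived diagnostic statistics (fractions in [0, 1]).

    ``plr`` is ``inf`` at perfect specificity (no false positives).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    plr: float
    nlr: float

    def as_percent(self) -> dict:
        """Report-style rounding: percentages to 1 decimal, ratios to 3."""
        return {
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "accuracy_pct": round(100 * self.accuracy, 1),
            "plr": math.inf if math.isinf(self.plr) else round(self.plr, 3),
            "nlr": round(self.nlr, 3),
        }


def confusion(preds: Sequence[bool], labels: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate binary predictions against true labels."""
    p = np.asarray(preds, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("preds and labels differ in length")
    return ConfusionTable(
        tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
        fn=int(np.sum(~p & y)), tn=int(np.sum(~p & ~y)))


def diagnostic_metrics(t: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy and likelihood ratios.

    sens = TP/(TP+FN); spec = TN/(TN+FP); PLR = sens/(1-spec) (``inf``
    when spec = 1); NLR = (1-sens)/spec.
    """
    if t.tp + t.fn == 0 or t.tn + t.fp == 0:
        raise ValueError("both classes must be present to derive metrics")
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.tn + t.fp)
    acc = (t.tp + t.tn) / t.total
    plr = math.inf if spec == 1.0 else sens / (1.0 - spec)
    nlr = math.inf if spec == 0.0 else (1.0 - sens) / spec
    return DiagnosticMetrics(sensitivity=sens, specificity=spec, accuracy=acc,
                             plr=plr, nlr=nlr)


def roc_auc(probs: Sequence[float], labels: Sequence[bool]
            ) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, and trapezoidal AUC.

    Tied scores enter the curve simultaneously.  Requires both classes.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probs, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair counts and the exact mid-p value."""

    b: int
    c: int
    p_mid: float


def mcnemar_midp(b: int, c: int) -> McNemarResult:
    """Exact mid-p McNemar test on discordant-pair counts.

    With ``n = b + c`` and ``k = min(b, c)``, the two-sided mid-p value
    is ``2 P(X <= k) - P(X = k)`` for ``X ~ Binomial(n, 1/2)``, clipped
    to [0, 1].  Undefined when there are no discordant pairs.
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        raise ValueError("no discordant pairs: mid-p McNemar is undefined")
    k = min(b, c)
    p = 2.0 * stats.binom.cdf(k, n, 0.5) - stats.binom.pmf(k, n, 0.5)
    return McNemarResult(b=b, c=c, p_mid=float(min(max(p, 0.0), 1.0)))


def discordant_counts(preds_a: Sequence[bool], preds_b: Sequence[bool],
                      labels: Sequence[bool]) -> Tuple[int, int]:
    """Paired-accuracy discordances: (A right & B wrong, A wrong & B right)."""
    a = np.asarray(preds_a, dtype=bool)
    bb = np.asarray(preds_b, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    a_ok = a == y
    b_ok = bb == y
    return int(np.sum(a_ok & ~b_ok)), int(np.sum(~a_ok & b_ok))
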