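"""Empirical ROC curve and AUC for a marker where LOW values flag disease.

Orientation matches the screening rule: a patient is test-positive when
the albumin-to-globulin ratio is at or below the threshold, so the true
positive rate at threshold t is the fraction of infected patients with
marker <= t. Ties take simultaneous vertical-plus-horizontal steps,
which makes the trapezoidal area equal to the Mann-Whitney concordance
probability P(X_inf < X_asep) + 0.5 P(X_inf = X_asep).

The AUC confidence interval defaults to DeLong's placement-value
variance; a stratified percentile bootstrap is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from scipy import stats

__all__ = ["ROCCurve", "roc_curve", "auc", "auc_ci"]


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (threshold, tpr, fpr) triples plus trapezoidal AUC.

    Points run from (fpr, tpr) = (0, 0) at threshold -inf to (1, 1) at
    +inf, with tpr and fpr non-decreasing along the way.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.tpr.tolist(), self.fpr.tolist()))


def _check_inputs(markers: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(markers, dtype=float)
    y = np.asarray(labels, dtype=int)
    if m.shape != y.shape or m.ndim != 1:
        raise ValueError("markers and labels must be equal-length 1-D sequences")
    if not np.all(np.isfinite(m)):
        raise ValueError("markers must be finite")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    return m, y


def roc_curve(markers: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC of a low-is-diseased marker against binary labels.

    Thresholds are the unique observed marker values plus -inf/+inf
    sentinels; at each threshold t the operating point is the confusion
    matrix of the rule positive iff marker <= t.
    """
    m, y = _check_inputs(markers, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    uniq = np.unique(m)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    pos_sorted = np.sort(m[y == 1])
    neg_sorted = np.sort(m[y == 0])
    tpr = np.searchsorted(pos_sorted, thresholds, side="right") / n_pos
    fpr = np.searchsorted(neg_sorted, thresholds, side="right") / n_neg
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=area, n_pos=n_pos, n_neg=n_neg
    )


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def _placements(m: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values under the low-is-diseased orientation.

    For infected i: V10_i = mean_j [x_i < y_j] + 0.5 [x_i == y_j] over
    aseptic j, and symmetrically for V01; computed via midranks.
    """
    pos = m[y == 1]
    neg = m[y == 0]
    npos, nneg = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    mid_all = stats.rankdata(combined, method="average")
    mid_pos = stats.rankdata(pos, method="average")
    mid_neg = stats.rankdata(neg, method="average")
    # infected below aseptic is concordant -> placement of a positive is
    # the fraction of negatives strictly above it (+ half ties)
    v10 = 1.0 - (mid_all[:npos] - mid_pos) / nneg
    v01 = (mid_all[npos:] - mid_neg) / npos
    return v10, v01


def auc_ci(
    markers: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    method: Literal["delong", "bootstrap"] = "delong",
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Confidence interval for the trapezoidal AUC, clipped to [0, 1].

    ``delong`` uses the placement-value variance with a normal interval;
    ``bootstrap`` is a percentile interval over class-stratified
    resamples (requires ``seed``).
    """
    m, y = _check_inputs(markers, labels)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 members per class")
    if method == "delong":
        v10, v01 = _placements(m, y)
        var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        a = float(v10.mean())
        half = z * np.sqrt(var)
        return max(0.0, a - half), min(1.0, a + half)
    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        pos = m[y == 1]
        neg = m[y == 0]
        aucs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            bm = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(len(bp), int), np.zeros(len(bn), int)])
            aucs[b] = roc_curve(bm, by).auc
        alpha = 1.0 - level
        lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
        return max(0.0, float(lo)), min(1.0, float(hi))
    raise ValueError(f"unknown method: {method!r}")
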