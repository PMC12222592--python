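"""2x2 diagnostic-accuracy metrics with exact binomial confidence intervals.

A patient tests positive when the albumin-to-globulin ratio falls at or
below the cutoff: infection depresses albumin and raises globulins, so
low AGR indicates infection. The boundary value itself counts as
positive, the conservative choice toward sensitivity in a screening
setting where a missed infection costs three times a false alarm.

Confidence intervals default to Clopper-Pearson (exact Beta-quantile)
with Wilson score intervals as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "ConfusionMatrix",
    "ProportionCI",
    "DiagnosticSummary",
    "classify",
    "confusion_matrix",
    "clopper_pearson",
    "wilson",
    "diagnostic_summary",
    "percent",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float
    method: Literal["clopper_pearson", "wilson"]

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValueError(
                f"need 0 <= lower <= estimate <= upper <= 1, got "
                f"({self.lower}, {self.estimate}, {self.upper})"
            )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity, specificity, predictive values and accuracy at a cutoff.

    A metric whose denominator is empty (e.g. PPV with no positives) is
    reported as None rather than raising; the others are still computed.
    LR+ and LR- are convenience fields without intervals.
    """

    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    accuracy: Optional[ProportionCI]
    lr_positive: Optional[float]
    lr_negative: Optional[float]

    def percents(self) -> dict[str, Optional[dict[str, int]]]:
        """Whole-percent rendering (round half up), journal style."""
        out: dict[str, Optional[dict[str, int]]] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            ci: Optional[ProportionCI] = getattr(self, name)
            out[name] = (
                None
                if ci is None
                else {
                    "estimate": percent(ci.estimate),
                    "lower": percent(ci.lower),
                    "upper": percent(ci.upper),
                }
            )
        return out


def percent(p: float) -> int:
    """Proportion -> whole percent, round half up (0.945 -> 95 at 94.5%)."""
    return int(math.floor(p * 100.0 + 0.5))


def classify(agr: float, cutoff: float) -> Literal["positive", "negative"]:
    """Screen one AGR value: positive (suspect infection) iff agr <= cutoff."""
    if not agr > 0:
        raise ValueError(f"AGR must be positive, got {agr}")
    return "positive" if agr <= cutoff else "negative"


def confusion_matrix(cohort: Cohort, cutoff: float) -> ConfusionMatrix:
    """2x2 table of the AGR screen at ``cutoff`` against infection status."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    agr = cohort.agr_values()
    infected = cohort.labels() == 1
    positive = agr <= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(infected & positive)),
        fp=int(np.sum(~infected & positive)),
        tn=int(np.sum(~infected & ~positive)),
        fn=int(np.sum(infected & ~positive)),
    )


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval from Beta quantiles.

    Lower bound is exactly 0 when successes = 0 and the upper exactly 1
    when successes = trials.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes)
    )
    return ProportionCI(
        estimate=successes / trials,
        lower=lower,
        upper=upper,
        level=level,
        method="clopper_pearson",
    )


def wilson(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval, offered as the non-exact alternative."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    p = successes / trials
    denom = 1.0 + z * z / trials
    centre = (p + z * z / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials)) / denom
    return ProportionCI(
        estimate=p,
        lower=max(0.0, centre - half),
        upper=min(1.0, centre + half),
        level=level,
        method="wilson",
    )


def diagnostic_summary(
    cm: ConfusionMatrix,
    level: float = 0.95,
    method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> DiagnosticSummary:
    """All accuracy metrics of a 2x2 table, each with its binomial CI."""
    ci = clopper_pearson if method == "clopper_pearson" else wilson

    def safe(successes: int, trials: int) -> Optional[ProportionCI]:
        return None if trials == 0 else ci(successes, trials, level)

    sens = safe(cm.tp, cm.tp + cm.fn)
    spec = safe(cm.tn, cm.tn + cm.fp)
    lr_pos = lr_neg = None
    if sens is not None and spec is not None:
        if spec.estimate < 1.0:
            lr_pos = sens.estimate / (1.0 - spec.estimate)
        if spec.estimate > 0.0:
            lr_neg = (1.0 - sens.estimate) / spec.estimate
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=safe(cm.tp, cm.tp + cm.fp),
        npv=safe(cm.tn, cm.tn + cm.fn),
        accuracy=safe(cm.tp + cm.tn, cm.total) if cm.total else None,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
    )
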