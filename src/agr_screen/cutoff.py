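"""Cost-weighted optimal cutoff selection with bootstrap internal validation.

The screening threshold is chosen to minimize a misclassification cost
cost_FP * FP + cost_FN * FN, with a false negative (missed infection)
weighted three times a false positive by default. To stabilize the
choice against sampling noise, the cohort is resampled with replacement
(B = 1000 by default) and the final cutoff minimizes the MEAN cost
across replicates on a candidate grid frozen from the original sample;
the per-replicate minimizers are retained as a dispersion diagnostic.

Candidate cutoffs are midpoints between consecutive distinct marker
values plus one sentinel on each side, so every achievable confusion
matrix is represented exactly once. Cost ties break toward the larger
cutoff, which under the low-AGR-is-positive polarity maximizes
sensitivity — consistent with the asymmetric cost.

For two log-normal populations the cost-optimal threshold has a closed
form (the density-ratio condition), used as the known-truth oracle when
validating recovery on synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .diagnostics import ConfusionMatrix

__all__ = [
    "CostSpec",
    "CutoffResult",
    "misclassification_cost",
    "candidate_cutoffs",
    "cost_curve",
    "optimal_cutoff_single",
    "bootstrap_optimal_cutoff",
    "lognormal_cost_optimal_threshold",
]


@dataclass(frozen=True)
class CostSpec:
    """Misclassification weights; default 3:1 against false negatives."""

    cost_fp: float = 1.0
    cost_fn: float = 3.0

    def __post_init__(self):
        if self.cost_fp <= 0 or self.cost_fn <= 0:
            raise ValueError("cost weights must be positive")


@dataclass
class CutoffResult:
    """Outcome of the bootstrap cutoff search."""

    cutoff: float
    mean_cost_at_cutoff: float
    n_bootstrap: int
    candidate_grid: np.ndarray
    seed: Optional[int]
    replicate_cutoff_median: float
    replicate_cutoff_iqr: tuple[float, float]
    replicate_cutoffs: Optional[np.ndarray] = field(default=None, repr=False)
    mean_costs: Optional[np.ndarray] = field(default=None, repr=False)


def misclassification_cost(cm: ConfusionMatrix, costs: CostSpec = CostSpec()) -> float:
    """cost_fp * FP + cost_fn * FN."""
    return costs.cost_fp * cm.fp + costs.cost_fn * cm.fn


def candidate_cutoffs(markers: Sequence[float]) -> np.ndarray:
    """Midpoints between distinct sorted marker values, plus sentinels.

    The low sentinel sits below the minimum and the high sentinel above
    the maximum, offset by half the smallest gap; grid size is
    (#distinct values) + 1 and each candidate induces a distinct
    confusion matrix.
    """
    uniq = np.unique(np.asarray(markers, dtype=float))
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct marker values")
    gaps = np.diff(uniq)
    delta = gaps.min() / 2.0
    mids = uniq[:-1] + gaps / 2.0
    return np.concatenate(([uniq[0] - delta], mids, [uniq[-1] + delta]))


def cost_curve(
    agr: np.ndarray,
    infected: np.ndarray,
    grid: np.ndarray,
    costs: CostSpec,
) -> np.ndarray:
    """Misclassification cost at every grid cutoff, via sorted searches.

    fn(c) = #infected with agr > c, fp(c) = #aseptic with agr <= c
    (positive iff agr <= c). O((n + g) log n); replicates missing one
    class simply contribute zero to that class's term.
    """
    pos_sorted = np.sort(agr[infected == 1])
    neg_sorted = np.sort(agr[infected == 0])
    fn = len(pos_sorted) - np.searchsorted(pos_sorted, grid, side="right")
    fp = np.searchsorted(neg_sorted, grid, side="right")
    return costs.cost_fp * fp + costs.cost_fn * fn


def _argmin_prefer_last(values: np.ndarray) -> int:
    """Index of the minimum, ties broken toward the largest index."""
    rev = values[::-1]
    return len(values) - 1 - int(np.argmin(rev))


def optimal_cutoff_single(
    cohort: Cohort, costs: CostSpec = CostSpec()
) -> tuple[float, float]:
    """Exhaustive cost minimization over the candidate grid of one sample.

    Ties break toward the larger cutoff (higher sensitivity).
    """
    agr = cohort.agr_values()
    y = cohort.labels()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both groups must be present")
    grid = candidate_cutoffs(agr)
    cost = cost_curve(agr, y, grid, costs)
    idx = _argmin_prefer_last(cost)
    return float(grid[idx]), float(cost[idx])


def bootstrap_optimal_cutoff(
    cohort: Cohort,
    costs: CostSpec = CostSpec(),
    n_bootstrap: int = 1000,
    seed: int = 0,
    keep_replicates: bool = False,
    stratified: bool = False,
) -> CutoffResult:
    """Bootstrap-stabilized cutoff: minimize mean cost over B resamples.

    Resampling is pooled over the whole cohort by default (the resample
    unit is the patient); ``stratified=True`` resamples each group to
    its own size instead. The candidate grid is frozen from the original
    sample so costs are comparable across replicates. Deterministic
    given ``seed``.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    agr = cohort.agr_values()
    y = cohort.labels()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both groups must be present")
    grid = candidate_cutoffs(agr)
    rng = np.random.default_rng(seed)
    n = len(agr)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)

    total = np.zeros(len(grid))
    rep_cutoffs = np.empty(n_bootstrap)
    n_usable = 0
    for b in range(n_bootstrap):
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
        cost_b = cost_curve(agr[idx], y[idx], grid, costs)
        total += cost_b
        rep_cutoffs[b] = grid[_argmin_prefer_last(cost_b)]
        if np.any(y[idx] == 1) and np.any(y[idx] == 0):
            n_usable += 1
    if n_usable == 0:
        raise RuntimeError("every bootstrap replicate was single-class")

    mean_cost = total / n_bootstrap
    idx_best = _argmin_prefer_last(mean_cost)
    q1, med, q3 = np.quantile(rep_cutoffs, [0.25, 0.5, 0.75])
    return CutoffResult(
        cutoff=float(grid[idx_best]),
        mean_cost_at_cutoff=float(mean_cost[idx_best]),
        n_bootstrap=n_bootstrap,
        candidate_grid=grid,
        seed=seed,
        replicate_cutoff_median=float(med),
        replicate_cutoff_iqr=(float(q1), float(q3)),
        replicate_cutoffs=rep_cutoffs if keep_replicates else None,
        mean_costs=mean_cost if keep_replicates else None,
    )


def lognormal_cost_optimal_threshold(
    mu_inf: float,
    sigma_inf: float,
    mu_asep: float,
    sigma_asep: float,
    costs: CostSpec = CostSpec(),
    n_inf: float = 1.0,
    n_asep: float = 1.0,
) -> float:
    """Analytic cost-minimizing threshold for two log-normal populations.

    The expected cost cost_fn*n_inf*P(X_inf > c) + cost_fp*n_asep*
    P(X_asep <= c) is stationary where the density ratio satisfies
    f_inf(c) / f_asep(c) = (cost_fp * n_asep) / (cost_fn * n_inf) — a
    quadratic in ln c. The root on the decreasing branch of the ratio is
    the minimum; requires sigma_inf != sigma_asep (distinct curvatures).
    """
    k = (costs.cost_fp * n_asep) / (costs.cost_fn * n_inf)
    s1sq, s2sq = sigma_inf**2, sigma_asep**2
    a = -1.0 / (2 * s1sq) + 1.0 / (2 * s2sq)
    if abs(a) < 1e-12:
        raise ValueError("equal sigmas: density ratio is monotone, no closed quadratic")
    b = mu_inf / s1sq - mu_asep / s2sq
    c0 = -mu_inf**2 / (2 * s1sq) + mu_asep**2 / (2 * s2sq) + math.log(
        sigma_asep / sigma_inf
    ) - math.log(k)
    disc = b * b - 4 * a * c0
    if disc < 0:
        raise ValueError("density ratio never attains the cost ratio")
    r1 = (-b - math.sqrt(disc)) / (2 * a)
    r2 = (-b + math.sqrt(disc)) / (2 * a)
    lo, hi = min(r1, r2), max(r1, r2)
    # a > 0 when sigma_inf > sigma_asep: log-ratio is an upward parabola,
    # decreasing branch (cost minimum) is the smaller root, and vice versa
    z = lo if a > 0 else hi
    return math.exp(z)
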