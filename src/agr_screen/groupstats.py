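"""Group-comparison statistics and the false-positive confounder analysis.

Covers the comparison table between infected and aseptic groups
(median/IQR with Mann-Whitney U for continuous variables, counts with
chi-squared or Fisher's exact test for categorical ones), Spearman
correlations of AGR against candidate confounders, and age-adjusted
logistic regression fitted by iteratively reweighted least squares —
one model per focal confounder with age always included, each reported
as a single coefficient row (B, SE, Wald, df, p, OR).

All p-values are two-sided. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, ConfigurationError
from .diagnostics import confusion_matrix

__all__ = [
    "GroupComparisonRow",
    "LogisticFitRow",
    "CorrelationResult",
    "FalsePositiveAnalysis",
    "mann_whitney_u",
    "chi_squared_or_fisher",
    "spearman",
    "logistic_fit",
    "irls_logistic",
    "compare_groups",
    "false_positive_analysis",
    "CONTINUOUS_VARIABLES",
    "CATEGORICAL_VARIABLES",
]

CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "age",
    "bmi",
    "cci",
    "esr",
    "crp",
    "sf_wbc",
    "sf_pmn",
    "agr",
    "inr",
    "creatinine",
    "uremia",
    "got",
    "gpt",
    "alp",
    "albumin",
    "globulin",
)
CATEGORICAL_VARIABLES: tuple[str, ...] = ("sex",)


@dataclass(frozen=True)
class GroupComparisonRow:
    """One comparison-table row: per-group summary plus the test."""

    variable: str
    group_a_summary: str
    group_b_summary: str
    test: Literal["mann_whitney", "chi_squared", "fisher_exact"]
    statistic: Optional[float]
    p_value: Optional[float]
    incomplete: bool = False


@dataclass(frozen=True)
class LogisticFitRow:
    """One logistic-regression report row for a focal variable."""

    variable: str
    b: float
    se: float
    wald: float
    df: int
    p_value: float
    or_: float
    converged: bool = True
    flagged: Optional[str] = None


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    rho: Optional[float]
    p_value: Optional[float]
    n_used: int


@dataclass
class FalsePositiveAnalysis:
    """Confounder work-up among aseptic patients: FP vs TN strata."""

    n_false_positive: int
    n_true_negative: int
    comparisons: list[GroupComparisonRow]
    correlations: list[CorrelationResult]
    logistic: list[LogisticFitRow]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    Exact enumeration when both samples have at most 8 observations and
    no ties; otherwise the normal approximation with tie-corrected
    variance and continuity correction. Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= 8 and y.size <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_squared_or_fisher(
    table: Sequence[Sequence[float]],
) -> tuple[Literal["chi_squared", "fisher_exact"], float, float]:
    """2x2 association test with the conventional selection rule.

    Pearson chi-squared without continuity correction, falling back to
    Fisher's exact test (two-sided, sum of tables no more probable than
    the observed) when any expected cell count is below 5. A zero
    marginal degenerates to Fisher with p = 1. Returns
    (test used, statistic, p); the Fisher statistic is the sample odds
    ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() <= 0:
        raise ValueError("need a non-negative 2x2 table with positive total")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        odds, p = stats.fisher_exact(t)
        return "fisher_exact", float(odds), float(p)
    expected = np.outer(rows, cols) / t.sum()
    if np.any(expected < 5):
        odds, p = stats.fisher_exact(t)
        return "fisher_exact", float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return "chi_squared", float(chi2), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with complete-case pair dropping.

    rho is the Pearson correlation of midranks; the two-sided p uses the
    t approximation with n - 2 degrees of freedom. A constant variable
    leaves rho undefined (None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(("x", "y"), None, None, n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(("x", "y"), float(rho), float(p), n)


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol_score: float = 1e-8,
    tol_llf: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool, list[float]]:
    """Logistic maximum likelihood by iteratively reweighted least squares.

    Newton steps with step-halving so the log-likelihood never
    decreases; converged when the largest score component falls below
    ``tol_score`` or the relative log-likelihood change below
    ``tol_llf``. Returns (beta, covariance, converged, llf history).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)

    def llf(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    history = [llf(beta)]
    converged = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood monotone
        scale = 1.0
        new = llf(beta + step)
        while new < history[-1] and scale > 1e-8:
            scale /= 2.0
            new = llf(beta + scale * step)
        beta = beta + scale * step
        history.append(new)
        if abs(history[-1] - history[-2]) <= tol_llf * (abs(history[-2]) + 1e-12):
            converged = True
            break
    eta = X @ beta
    w = expit(eta) * (1.0 - expit(eta))
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        pass
    return beta, cov, converged, history


def logistic_fit(
    outcome: Sequence[int],
    predictors: pd.DataFrame,
    adjust_for: Optional[str] = None,
) -> list[LogisticFitRow]:
    """One age-adjusted (or unadjusted) model per focal predictor.

    For each column of ``predictors`` other than ``adjust_for``, fits
    outcome ~ intercept + focal [+ adjust_for] on complete cases and
    reports the focal coefficient with its Wald test (df = 1) and odds
    ratio. Non-convergence or quasi-separation (diverging coefficient)
    yields a flagged row rather than silent output.
    """
    y_all = np.asarray(outcome, dtype=float)
    if set(np.unique(y_all[np.isfinite(y_all)])) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if adjust_for is not None and adjust_for not in predictors.columns:
        raise ConfigurationError(f"adjustment covariate {adjust_for!r} not in predictors")
    rows: list[LogisticFitRow] = []
    for col in predictors.columns:
        if col == adjust_for:
            continue
        cols = [col] + ([adjust_for] if adjust_for else [])
        block = predictors[cols].to_numpy(dtype=float)
        keep = np.isfinite(y_all) & np.all(np.isfinite(block), axis=1)
        yb = y_all[keep]
        Xb = np.column_stack([np.ones(keep.sum()), block[keep]])
        flagged = None
        if len(np.unique(yb)) < 2:
            flagged = "outcome constant on complete cases"
        elif any(np.unique(Xb[:, j]).size < 2 for j in range(1, Xb.shape[1])):
            flagged = "constant predictor on complete cases"
        if flagged is not None:
            rows.append(
                LogisticFitRow(col, np.nan, np.nan, np.nan, 1, np.nan, np.nan, False, flagged)
            )
            continue
        beta, cov, converged, _ = irls_logistic(Xb, yb)
        b = float(beta[1])
        se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) and cov[1, 1] > 0 else np.nan
        if not converged:
            flagged = "IRLS did not converge"
        elif abs(b) > 15 or (np.isfinite(se) and se > 1e3):
            # diverging coefficient or exploding SE: (quasi-)separation
            flagged = "separation suspected (|b| diverging)"
        wald = (b / se) ** 2 if np.isfinite(se) and se > 0 else np.nan
        p = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else np.nan
        rows.append(
            LogisticFitRow(
                variable=col,
                b=b,
                se=se,
                wald=float(wald) if np.isfinite(wald) else np.nan,
                df=1,
                p_value=p,
                or_=float(np.exp(b)),
                converged=converged,
                flagged=flagged,
            )
        )
    return rows


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return f"{med:.4g} (IQR {q1:.4g}–{q3:.4g})"


def _compare_one(
    variable: str, a: np.ndarray, b: np.ndarray
) -> GroupComparisonRow:
    """Continuous comparison of two complete-case samples."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return GroupComparisonRow(variable, "—", "—", "mann_whitney", None, None, True)
    u, p = mann_whitney_u(a, b)
    return GroupComparisonRow(variable, _median_iqr(a), _median_iqr(b), "mann_whitney", u, p)


def _compare_binary(
    variable: str, a: np.ndarray, b: np.ndarray
) -> GroupComparisonRow:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return GroupComparisonRow(variable, "—", "—", "chi_squared", None, None, True)
    ka, kb = int(a.sum()), int(b.sum())
    table = [[ka, a.size - ka], [kb, b.size - kb]]
    test, statistic, p = chi_squared_or_fisher(table)
    return GroupComparisonRow(
        variable,
        f"{ka} ({100 * ka / a.size:.0f}%)",
        f"{kb} ({100 * kb / b.size:.0f}%)",
        test,
        statistic,
        p,
    )


def compare_groups(cohort: Cohort, variables: Sequence[str]) -> list[GroupComparisonRow]:
    """Comparison-table rows: infected (group A) vs aseptic (group B)."""
    y = cohort.labels()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("cohort must contain both groups")
    rows = []
    for var in variables:
        if var in CATEGORICAL_VARIABLES:
            vals = cohort.values(var)
            rows.append(_compare_binary(var, vals[y == 1], vals[y == 0]))
        elif var in CONTINUOUS_VARIABLES:
            vals = cohort.values(var)
            rows.append(_compare_one(var, vals[y == 1], vals[y == 0]))
        else:
            raise ConfigurationError(f"unknown variable: {var!r}")
    return rows


def false_positive_analysis(
    cohort: Cohort,
    cutoff: float,
    confounders: Sequence[str],
    adjust_for: str = "age",
) -> FalsePositiveAnalysis:
    """Why do uninfected patients screen positive?

    Restricted to aseptic patients, split by the AGR test at ``cutoff``
    into false positives (AGR <= cutoff) and true negatives. Runs the
    group comparison on each confounder, Spearman correlations of AGR
    against each confounder across the whole aseptic subset, and
    age-adjusted logistic models with FP status as the outcome, one
    focal confounder at a time.
    """
    y = cohort.labels()
    aseptic = cohort.subset(list(y == 0))
    if len(aseptic) == 0:
        raise ValueError("no aseptic patients in cohort")
    agr = aseptic.agr_values()
    fp_mask = agr <= cutoff
    if not np.any(fp_mask):
        raise ValueError("no false-positive stratum at this cutoff")
    if not np.any(~fp_mask):
        raise ValueError("no true-negative stratum at this cutoff")

    comparisons: list[GroupComparisonRow] = []
    correlations: list[CorrelationResult] = []
    for var in confounders:
        vals = aseptic.values(var)
        if var in CATEGORICAL_VARIABLES:
            comparisons.append(_compare_binary(var, vals[fp_mask], vals[~fp_mask]))
            continue
        comparisons.append(_compare_one(var, vals[fp_mask], vals[~fp_mask]))
        keep = np.isfinite(vals)
        if keep.sum() >= 3:
            res = spearman(agr[keep], vals[keep])
            correlations.append(
                CorrelationResult(("agr", var), res.rho, res.p_value, res.n_used)
            )
        else:
            correlations.append(CorrelationResult(("agr", var), None, None, int(keep.sum())))

    predictors = pd.DataFrame(
        {var: aseptic.values(var) for var in list(confounders) + [adjust_for]}
    )
    # drop duplicated adjustment column if it is also a confounder
    predictors = predictors.loc[:, ~predictors.columns.duplicated()]
    logistic = logistic_fit(fp_mask.astype(int), predictors, adjust_for=adjust_for)
    return FalsePositiveAnalysis(
        n_false_positive=int(fp_mask.sum()),
        n_true_negative=int((~fp_mask).sum()),
        comparisons=comparisons,
        correlations=correlations,
        logistic=logistic,
    )
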