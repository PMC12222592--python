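"""Full study replication behind one entry point.

Stage order: load or simulate a cohort, validate it, compare the
infected and aseptic groups, select the screening cutoff by
cost-weighted bootstrap (unless overridden), build the ROC curve with
its AUC interval, evaluate 2x2 diagnostic accuracy at the selected
cutoff, and profile the false-positive stratum for confounders. The
report embeds every stage output together with the configuration and
seed, so re-running the same configuration reproduces it byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .cohort import Cohort, read_cohort_csv, validate_cohort
from .cutoff import CostSpec, bootstrap_optimal_cutoff
from .diagnostics import confusion_matrix, diagnostic_summary
from .groupstats import false_positive_analysis
from .roc import auc_ci, roc_curve
from .synthetic import CohortSpec, default_table1_spec, generate_cohort, load_cohort_spec

log = logging.getLogger("agr_screen")

__all__ = ["AnalysisConfig", "StudyReport", "run_full_analysis", "render_report", "parse_report"]

DEFAULT_CONFOUNDERS: tuple[str, ...] = (
    "bmi",
    "creatinine",
    "uremia",
    "got",
    "gpt",
    "inr",
    "alp",
)


class AnalysisConfig(BaseModel):
    """Configuration of one full run; exactly one input source."""

    model_config = ConfigDict(frozen=True)

    input_path: Optional[str] = None
    simulate_spec: Optional[str] = None  # path to a CohortSpec JSON, or "default"
    seed: int = 0
    cost_fp: float = 1.0
    cost_fn: float = 3.0
    n_bootstrap: int = 1000
    level: float = 0.95
    cutoff_override: Optional[float] = None
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    with_false_positive_block: bool = True
    auc_ci_method: Literal["delong", "bootstrap"] = "delong"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_path is None) == (self.simulate_spec is None):
            raise ValueError("set exactly one of input_path / simulate_spec")
        return self


class StudyReport(BaseModel):
    """Machine-readable report of the whole analysis; schema = this model."""

    version: str
    config: AnalysisConfig
    cohort_summary: dict
    group_comparison: list[dict]
    cutoff: dict
    roc: dict
    diagnostics: dict
    false_positive: Optional[dict]


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort_csv(config.input_path)
    if config.simulate_spec == "default":
        spec = default_table1_spec(seed=config.seed)
    else:
        spec = load_cohort_spec(config.simulate_spec, seed=config.seed)
    return generate_cohort(spec)


def run_full_analysis(config: AnalysisConfig) -> StudyReport:
    """Execute every stage and assemble the report.

    Any stage failure propagates with the stage name attached; no
    partial report is produced.
    """
    stages: list[tuple[str, float]] = []

    def stage(name: str):
        log.info("stage %s (seed=%s)", name, config.seed)
        stages.append((name, time.perf_counter()))

    try:
        stage("load")
        cohort = _load_cohort(config)

        stage("validate")
        violations = validate_cohort(cohort)
        if violations:
            raise ValueError(
                f"cohort failed validation: {len(violations)} violation(s), "
                f"first: {violations[0]}"
            )

        stage("compare_groups")
        from .groupstats import CONTINUOUS_VARIABLES, compare_groups

        present = [
            v
            for v in ("age", "sex", "bmi", "cci", "esr", "crp", "sf_wbc", "sf_pmn", "agr")
            if v == "sex" or np.any(np.isfinite(cohort.values(v)))
        ]
        comparison = compare_groups(cohort, present)

        costs = CostSpec(cost_fp=config.cost_fp, cost_fn=config.cost_fn)
        if config.cutoff_override is not None:
            stage("cutoff (override)")
            cutoff_block = {
                "cutoff": config.cutoff_override,
                "source": "override",
            }
            selected = config.cutoff_override
        else:
            stage("cutoff (bootstrap)")
            res = bootstrap_optimal_cutoff(
                cohort, costs, n_bootstrap=config.n_bootstrap, seed=config.seed
            )
            cutoff_block = {
                "cutoff": res.cutoff,
                "source": "bootstrap_mean_cost",
                "mean_cost_at_cutoff": res.mean_cost_at_cutoff,
                "n_bootstrap": res.n_bootstrap,
                "replicate_cutoff_median": res.replicate_cutoff_median,
                "replicate_cutoff_iqr": list(res.replicate_cutoff_iqr),
                "seed": res.seed,
            }
            selected = res.cutoff

        stage("roc")
        markers = cohort.agr_values()
        labels = cohort.labels()
        curve = roc_curve(markers, labels)
        lo, hi = auc_ci(
            markers,
            labels,
            level=config.level,
            method=config.auc_ci_method,
            seed=config.seed,
        )
        roc_block = {
            "auc": curve.auc,
            "auc_ci": [lo, hi],
            "auc_ci_method": config.auc_ci_method,
            "level": config.level,
            "n_pos": curve.n_pos,
            "n_neg": curve.n_neg,
            "points": [
                {"threshold": t, "tpr": tp, "fpr": fp}
                for t, tp, fp in curve.points
                if np.isfinite(t)
            ],
        }

        stage("diagnostic_summary")
        cm = confusion_matrix(cohort, selected)
        summary = diagnostic_summary(cm, level=config.level)
        diag_block = {
            "cutoff": selected,
            "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "percent": summary.percents(),
            "raw": {
                name: (
                    None
                    if getattr(summary, name) is None
                    else {
                        "estimate": getattr(summary, name).estimate,
                        "lower": getattr(summary, name).lower,
                        "upper": getattr(summary, name).upper,
                    }
                )
                for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
            },
            "lr_positive": summary.lr_positive,
            "lr_negative": summary.lr_negative,
        }

        fp_block = None
        if config.with_false_positive_block:
            stage("false_positive_analysis")
            fpa = false_positive_analysis(cohort, selected, config.confounders)
            fp_block = {
                "n_false_positive": fpa.n_false_positive,
                "n_true_negative": fpa.n_true_negative,
                "comparisons": [vars(r) for r in fpa.comparisons],
                "correlations": [
                    {
                        "pair": list(r.variable_pair),
                        "rho": r.rho,
                        "p_value": r.p_value,
                        "n_used": r.n_used,
                    }
                    for r in fpa.correlations
                ],
                "logistic": [_logistic_row_dict(r) for r in fpa.logistic],
            }
    except Exception as exc:
        name = stages[-1][0] if stages else "init"
        raise RuntimeError(
            f"analysis failed at stage {name!r} with config "
            f"{config.model_dump_json()}: {exc}"
        ) from exc

    for (name, t0), (_, t1) in zip(stages, stages[1:]):
        log.info("stage %s took %.3fs", name, t1 - t0)

    return StudyReport(
        version=__version__,
        config=config,
        cohort_summary={
            "n": len(cohort),
            "n_infected": cohort.n_infected,
            "n_aseptic": cohort.n_aseptic,
            "provenance": cohort.provenance,
            "seed": cohort.seed,
        },
        group_comparison=[vars(r) for r in comparison],
        cutoff=cutoff_block,
        roc=roc_block,
        diagnostics=diag_block,
        false_positive=fp_block,
    )


def _logistic_row_dict(r) -> dict:
    d = vars(r).copy()
    for key, val in d.items():
        if isinstance(val, float) and not np.isfinite(val):
            d[key] = None
    return d


def render_report(report: StudyReport, format: Literal["json", "markdown"] = "json") -> str:
    """Serialize a report; JSON round-trips through :func:`parse_report`."""
    if format == "json":
        return report.model_dump_json(indent=2)
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown format: {format!r}")


def parse_report(text: str) -> StudyReport:
    """Inverse of the JSON rendering (schema-validating)."""
    return StudyReport.model_validate(json.loads(text))


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "—"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _render_markdown(report: StudyReport) -> str:
    lines: list[str] = []
    cs = report.cohort_summary
    lines.append("# AGR diagnostic work-up report")
    lines.append("")
    lines.append(
        f"Cohort: n = {cs['n']} ({cs['n_infected']} infected, "
        f"{cs['n_aseptic']} aseptic), provenance {cs['provenance']}."
    )
    lines.append("")
    lines.append("## Group comparison")
    lines.append("")
    lines.append("| Variable | Infected | Aseptic | Test | p-value |")
    lines.append("|---|---|---|---|---|")
    for row in report.group_comparison:
        lines.append(
            f"| {row['variable']} | {row['group_a_summary']} | "
            f"{row['group_b_summary']} | {row['test']} | {_fmt_p(row['p_value'])} |"
        )
    lines.append("")
    lines.append("## Cutoff")
    lines.append("")
    lines.append(f"Selected AGR cutoff: **{report.cutoff['cutoff']:.4g}** "
                 f"(source: {report.cutoff['source']}).")
    lines.append("")
    lines.append("## ROC")
    lines.append("")
    roc = report.roc
    lines.append(
        f"AUC {roc['auc']:.2f} ({int(roc['level'] * 100)}% CI "
        f"{roc['auc_ci'][0]:.2f}–{roc['auc_ci'][1]:.2f}, {roc['auc_ci_method']})."
    )
    lines.append("")
    lines.append("## Diagnostic accuracy")
    lines.append("")
    lines.append("| Metric | Estimate | CI |")
    lines.append("|---|---|---|")
    pct = report.diagnostics["percent"]
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        v = pct[name]
        if v is None:
            lines.append(f"| {name} | — | — |")
        else:
            lines.append(f"| {name} | {v['estimate']}% | {v['lower']}–{v['upper']}% |")
    if report.false_positive is not None:
        fp = report.false_positive
        lines.append("")
        lines.append("## False-positive confounder analysis")
        lines.append("")
        lines.append(
            f"{fp['n_false_positive']} false positives vs "
            f"{fp['n_true_negative']} true negatives among aseptic patients."
        )
        lines.append("")
        lines.append("| Variable | B | S.E. | Wald | df | p-value | OR |")
        lines.append("|---|---|---|---|---|---|---|")
        for row in fp["logistic"]:
            if row["b"] is None:
                lines.append(f"| {row['variable']} | — (flagged: {row['flagged']}) | | | | | |")
            else:
                lines.append(
                    f"| {row['variable']} | {row['b']:.3f} | {row['se']:.3f} | "
                    f"{row['wald']:.3f} | {row['df']} | {_fmt_p(row['p_value'])} | "
                    f"{row['or_']:.2f} |"
                )
    lines.append("")
    return "\n".join(lines)
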