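"""End-to-end study orchestration: cohort -> exclusions -> scores -> tables.

``run_study`` takes either a list of registry records or a synthetic-cohort
configuration, applies the inclusion rules, computes the four-score panel
per patient, and assembles the discrimination report: cohort summary, AUC
table with DeLong CIs, the pairwise paired-AUC p-value matrix, and the
Youden-optimal cutoff table. ``render_report`` serialises the report as one
CSV per table plus an ROC overlay figure and a run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .registry import PatientRecord, ValidationIssue, validate_record
from .scores import score_panel
from .synthetic import (
    CohortSummary,
    SyntheticConfig,
    calibrate_defaults,
    generate_cohort,
    summarize_cohort,
)
from .validation import (
    SCORE_ORIENTATIONS,
    AUCResult,
    CutoffReport,
    PairedComparison,
    pairwise_auc_table,
    roc_points,
    youden_optimal_cutoff,
)

__all__ = ["ValidationReport", "run_study", "render_report", "format_p"]

SCORE_NAMES = tuple(SCORE_ORIENTATIONS)


@dataclass
class ValidationReport:
    """Everything the study computes, recomputable from ``records``."""

    cohort_summary: CohortSummary
    auc_table: dict[str, AUCResult]
    pairwise: pd.DataFrame
    comparisons: list[PairedComparison]
    cutoff_table: dict[str, CutoffReport]
    exclusions: list[ValidationIssue]
    issues: list[ValidationIssue]
    n_input: int
    n_analyzed: int
    records: list[PatientRecord]
    panels: pd.DataFrame
    events: np.ndarray
    provenance: dict = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)


def run_study(
    records: Optional[Sequence[PatientRecord]] = None,
    config: Optional[SyntheticConfig] = None,
) -> ValidationReport:
    """Run the full analysis on a cohort (given or synthesised).

    Exactly one of ``records``/``config`` is typically supplied; with
    neither, the packaged calibrated synthetic cohort is used. Records with
    fatal validation issues are excluded and logged; a post-exclusion
    outcome vector with no deaths or no survivors is a hard error.
    """
    if records is not None and config is not None:
        raise ValueError("pass either records or a synthetic config, not both")
    provenance: dict = {"tool": "traumascore", "version": __version__}
    if records is None:
        config = config or calibrate_defaults()
        records = generate_cohort(config)
        provenance["input"] = "synthetic"
        provenance["seed"] = config.seed
        provenance["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
    else:
        records = list(records)
        provenance["input"] = "registry"

    log: list[str] = []
    analyzed: list[PatientRecord] = []
    exclusions: list[ValidationIssue] = []
    all_issues: list[ValidationIssue] = []
    for record in records:
        issues = validate_record(record)
        all_issues.extend(issues)
        for issue in issues:
            log.append(
                f"{'EXCLUDE' if issue.fatal else 'WARN'} "
                f"{issue.patient_id} [{issue.rule}]: {issue.message}"
            )
        fatal = [issue for issue in issues if issue.fatal]
        if fatal:
            exclusions.extend(fatal)
        else:
            analyzed.append(record)
    n_excluded_records = len(records) - len(analyzed)
    assert len(analyzed) + n_excluded_records == len(records)

    if not analyzed:
        raise ValueError("no records remain after exclusions")
    events = np.array([rec.died for rec in analyzed], dtype=bool)
    if events.all() or not events.any():
        raise ValueError(
            "degenerate outcome vector after exclusions "
            f"({int(events.sum())}/{len(events)} deaths); exclusion log: "
            + "; ".join(log[-10:])
        )

    panels_objects = [score_panel(rec) for rec in analyzed]
    panels = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in analyzed],
            "iss": [p.iss for p in panels_objects],
            "niss": [p.niss for p in panels_objects],
            "rts": [p.rts for p in panels_objects],
            "ps_mtos": [p.ps_mtos for p in panels_objects],
            "ps_ntrd": [p.ps_ntrd for p in panels_objects],
        }
    )

    aucs, p_matrix, comparisons = pairwise_auc_table(panels, events)
    cutoffs = {
        name: youden_optimal_cutoff(
            panels[name].to_numpy(), events, SCORE_ORIENTATIONS[name]
        )
        for name in SCORE_NAMES
    }
    for name, rep in cutoffs.items():
        if np.isnan(rep.ppv) or np.isnan(rep.npv):
            log.append(f"WARN {name}: undefined PPV/NPV at cutoff {rep.cutoff}")

    return ValidationReport(
        cohort_summary=summarize_cohort(analyzed),
        auc_table=aucs,
        pairwise=p_matrix,
        comparisons=comparisons,
        cutoff_table=cutoffs,
        exclusions=exclusions,
        issues=all_issues,
        n_input=len(records),
        n_analyzed=len(analyzed),
        records=analyzed,
        panels=panels,
        events=events,
        provenance=provenance,
        log_lines=log,
    )


def format_p(p: float) -> str:
    """Two-sided p-value for display, Table-3 style."""
    return "< 0.001" if p < 1e-3 else f"{p:.4f}"


def render_report(
    report: ValidationReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("svg",),
) -> list[Path]:
    """Write the report tables, the ROC overlay figure and a run log.

    Emits ``cohort_summary.csv``, ``auc_table.csv``, ``pairwise_p.csv``,
    ``cutoffs.csv``, ``roc_overlay.<fmt>``, ``provenance.yaml`` and
    ``run_log.txt``. Numeric cells carry six decimals, so reloading a CSV
    reproduces the report values well past the displayed precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cs = report.cohort_summary
    summary_rows = [
        ("n", cs.n),
        ("mortality_fraction", round(cs.mortality_fraction, 6)),
        ("age_mean", round(cs.age_mean, 6)),
        ("age_sd", round(cs.age_sd, 6)),
        ("male_fraction", round(cs.male_fraction, 6)),
        ("blunt_fraction", round(cs.mechanism_fractions["blunt"], 6)),
        ("penetrating_fraction", round(cs.mechanism_fractions["penetrating"], 6)),
        ("blast_fraction", round(cs.mechanism_fractions["blast"], 6)),
        ("niss_mean", round(cs.niss_mean, 6)),
        ("niss_sd", round(cs.niss_sd, 6)),
        ("rts_mean", round(cs.rts_mean, 6)),
        ("rts_sd", round(cs.rts_sd, 6)),
        ("ps_mtos_mean", round(cs.ps_mtos_mean, 6)),
        ("ps_ntrd_mean", round(cs.ps_ntrd_mean, 6)),
    ]
    path = out / "cohort_summary.csv"
    pd.DataFrame(summary_rows, columns=["statistic", "value"]).to_csv(path, index=False)
    written.append(path)

    path = out / "auc_table.csv"
    pd.DataFrame(
        [
            {
                "score": name,
                "auc": round(res.auc, 6),
                "se": round(res.se, 6),
                "ci_low": round(res.ci_low, 6),
                "ci_high": round(res.ci_high, 6),
            }
            for name, res in report.auc_table.items()
        ]
    ).to_csv(path, index=False)
    written.append(path)

    path = out / "pairwise_p.csv"
    report.pairwise.round(6).to_csv(path, index_label="score")
    written.append(path)

    path = out / "cutoffs.csv"
    pd.DataFrame(
        [
            {
                "score": name,
                "cutoff": round(rep.cutoff, 6),
                "direction": rep.direction,
                "sensitivity": round(rep.sensitivity, 6),
                "specificity": round(rep.specificity, 6),
                "accuracy": round(rep.accuracy, 6),
                "ppv": round(rep.ppv, 6),
                "npv": round(rep.npv, 6),
                "youden_j": round(rep.youden_j, 6),
            }
            for name, rep in report.cutoff_table.items()
        ]
    ).to_csv(path, index=False)
    written.append(path)

    for fmt in formats:
        fig_path = out / f"roc_overlay.{fmt}"
        _plot_roc_overlay(report, fig_path)
        written.append(fig_path)

    path = out / "provenance.yaml"
    path.write_text(yaml.safe_dump(report.provenance, sort_keys=True))
    written.append(path)

    path = out / "run_log.txt"
    header = [
        f"records read: {report.n_input}",
        f"records analyzed: {report.n_analyzed}",
        f"records excluded: {report.n_input - report.n_analyzed}",
    ]
    path.write_text("\n".join(header + report.log_lines) + "\n")
    written.append(path)
    return written


def _plot_roc_overlay(report: ValidationReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for name in SCORE_NAMES:
        curve = roc_points(
            report.panels[name].to_numpy(), report.events, SCORE_ORIENTATIONS[name]
        )
        auc = report.auc_table[name].auc
        ax.plot(curve.fpr, curve.tpr, label=f"{name.upper()} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title("ROC curves for in-hospital mortality")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
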