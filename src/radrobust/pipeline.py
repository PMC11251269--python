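"""Per-scenario orchestration and cross-scenario summaries.

One scenario run walks every feature through the study workflow:

1. full-grid metrics → robust / non-robust flag;
2. for each non-robust feature, the robustness matrix → conditionally
   robust (with robust range and margin) or non-robust;
3. for the same non-robust pool, dependency correction → correctable /
   moderately correctable / not correctable — range conditions and
   correction are alternative mitigations, so both are always computed;
4. margins of the conditionally robust features → the scenario's global
   robustness range.

Canonical outputs are tidy CSVs with fixed float formatting, so re-running
with identical inputs and configuration yields byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correction import CorrectabilityCategory, CorrectionResult, correct_feature
from .grids import ParameterGrid, RobustCriteria
from .io import FLOAT_FORMAT, FeatureTable, write_feature_table
from .metrics import compute_metrics, is_robust
from .ranges import (
    ConditionalCategory,
    GlobalRangeResult,
    RobustnessRange,
    aggregate_global_range,
    classify_conditional,
    compute_robustness_matrix,
    matrix_to_frame,
)

__all__ = ["ScenarioReport", "run_scenario", "summarise", "write_report"]

logger = logging.getLogger("radrobust")


@dataclass
class ScenarioReport:
    """Everything one scenario run produced, feature by feature."""

    grid: ParameterGrid
    rows: pd.DataFrame
    metrics: pd.DataFrame
    matrices: dict[str, pd.DataFrame]
    ranges: dict[str, RobustnessRange]
    corrections: dict[str, CorrectionResult]
    global_range: GlobalRangeResult | None

    @property
    def scenario(self) -> str:
        return self.grid.name

    def counts(self) -> dict[str, int]:
        c = {
            "robust": int(self.rows["robust"].sum()),
            "conditionally_robust": int(
                (
                    self.rows["conditional_category"]
                    == ConditionalCategory.CONDITIONALLY_ROBUST.value
                ).sum()
            ),
            "non_robust": int(
                (
                    self.rows["conditional_category"]
                    == ConditionalCategory.NON_ROBUST.value
                ).sum()
            ),
        }
        for cat in CorrectabilityCategory:
            c[cat.value] = int(
                (self.rows["correctability_category"] == cat.value).sum()
            )
        return c


def _interval_text(interval: tuple[float, float] | None) -> str:
    if interval is None:
        return ""
    return f"{interval[0]:g}..{interval[1]:g}"


def run_scenario(
    table: FeatureTable,
    grid: ParameterGrid,
    criteria: RobustCriteria = RobustCriteria(),
) -> ScenarioReport:
    """Full categorisation workflow for every feature of one scenario."""
    sub = table.require_complete(grid)  # errors before any stage runs
    features = sub.feature_names
    logger.info("scenario %s: %d features enter", grid.name, len(features))

    metric_rows = []
    rows = []
    matrices: dict[str, pd.DataFrame] = {}
    ranges: dict[str, RobustnessRange] = {}
    corrections: dict[str, CorrectionResult] = {}

    for feat in features:
        m = compute_metrics(sub, feat, grid)
        robust = is_robust(m, criteria)
        metric_rows.append(
            {
                "feature_name": feat,
                "scenario": grid.name,
                "cv_mean": m.cv_mean,
                "rrm": m.rrm,
                "rrm_abs": m.rrm_abs,
                "rrm_ci_low": m.rrm_ci_low,
                "rrm_ci_high": m.rrm_ci_high,
                "n_degenerate_subjects": m.n_degenerate_subjects,
                "flags": ",".join(sorted(m.degenerate_flags)),
                "robust": robust,
            }
        )
        row = {
            "feature_name": feat,
            "scenario": grid.name,
            "robust": robust,
            "conditional_category": "not_applicable",
            "robust_range": "",
            "margin": "",
            "correctability_category": "not_applicable",
            "best_function": "",
            "delta_cv": np.nan,
            "delta_rrm": np.nan,
        }
        if not robust:
            matrix = compute_robustness_matrix(sub, feat, grid, criteria)
            matrices[feat] = matrix_to_frame(matrix)
            rng = classify_conditional(matrix)
            ranges[feat] = rng
            row["conditional_category"] = rng.category.value
            row["robust_range"] = _interval_text(rng.in_units("robust_range"))
            row["margin"] = _interval_text(rng.in_units("margin"))

            corr = correct_feature(sub, feat, grid, criteria)
            corrections[feat] = corr
            row["correctability_category"] = corr.category.value
            if corr.best_model is not None:
                row["best_function"] = corr.best_model.function_id.value
            row["delta_cv"] = corr.delta_cv
            row["delta_rrm"] = corr.delta_rrm
        rows.append(row)

    cond = [
        r
        for r in ranges.values()
        if r.category is ConditionalCategory.CONDITIONALLY_ROBUST
    ]
    global_range = (
        aggregate_global_range(list(ranges.values()), grid) if cond else None
    )

    report = ScenarioReport(
        grid=grid,
        rows=pd.DataFrame(rows),
        metrics=pd.DataFrame(metric_rows),
        matrices=matrices,
        ranges=ranges,
        corrections=corrections,
        global_range=global_range,
    )
    logger.info("scenario %s: category counts %s", grid.name, report.counts())
    return report


def summarise(reports: list[ScenarioReport]) -> pd.DataFrame:
    """Counts and proportions per category per scenario, plus the list of
    features robust in every scenario."""
    if not reports:
        raise ValueError("nothing to summarise")
    rows = []
    for rep in reports:
        counts = rep.counts()
        total = len(rep.rows)
        row: dict[str, object] = {"scenario": rep.scenario, "n_features": total}
        for key, val in counts.items():
            row[f"n_{key}"] = val
            row[f"p_{key}"] = val / total if total else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    robust_sets = [
        set(rep.rows.loc[rep.rows["robust"], "feature_name"])
        for rep in reports
    ]
    always_robust = sorted(set.intersection(*robust_sets))
    summary.attrs["always_robust"] = always_robust
    return summary


def write_report(report: ScenarioReport, outdir: str | Path) -> None:
    """Write the canonical CSV outputs of one scenario run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = {"index": False, "float_format": FLOAT_FORMAT}
    report.metrics.to_csv(outdir / "metrics.csv", **kw)
    report.rows.to_csv(outdir / "report.csv", **kw)
    if report.matrices:
        pd.concat(report.matrices.values(), ignore_index=True).to_csv(
            outdir / "matrix.csv", **kw
        )
    if report.ranges:
        pd.DataFrame(
            [
                {
                    "feature_name": r.feature_name,
                    "category": r.category.value,
                    "robust_range": _interval_text(r.in_units("robust_range")),
                    "margin": _interval_text(r.in_units("margin")),
                }
                for r in report.ranges.values()
            ]
        ).to_csv(outdir / "ranges.csv", **kw)
    if report.global_range is not None:
        g = report.global_range
        pd.DataFrame(
            [
                {
                    "scenario": report.scenario,
                    "n_conditionally_robust": g.n_conditionally_robust,
                    "cutoff": g.cutoff,
                    "global_range_low": g.in_units()[0],
                    "global_range_high": g.in_units()[1],
                    "argmax_values_margin": ";".join(
                        f"{v:g}" for v in g.argmax_values_margin
                    ),
                    "argmax_values_robust_range": ";".join(
                        f"{v:g}" for v in g.argmax_values_robust_range
                    ),
                }
            ]
        ).to_csv(outdir / "global_range.csv", **kw)
    if report.corrections:
        pd.DataFrame(
            [
                {
                    "feature_name": c.feature_name,
                    **{f"aic_{k}": v for k, v in c.all_aics.items()},
                    "best_function": (
                        c.best_model.function_id.value
                        if c.best_model
                        else ""
                    ),
                    "alpha": c.best_model.alpha if c.best_model else np.nan,
                    "beta": c.best_model.beta if c.best_model else np.nan,
                    "cv_mean_before": c.metrics_before.cv_mean,
                    "cv_mean_after": (
                        c.metrics_after.cv_mean if c.metrics_after else np.nan
                    ),
                    "rrm_abs_before": c.metrics_before.rrm_abs,
                    "rrm_abs_after": (
                        c.metrics_after.rrm_abs if c.metrics_after else np.nan
                    ),
                    "wilcoxon_p": c.wilcoxon_p,
                    "ci_overlap": c.ci_overlap,
                    "category": c.category.value,
                    "reason": c.reason,
                }
                for c in report.corrections.values()
            ]
        ).to_csv(outdir / "correction.csv", **kw)
        for feat, c in report.corrections.items():
            if c.corrected_table is not None:
                write_feature_table(
                    c.corrected_table,
                    outdir / f"corrected_{feat}.csv",
                )
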