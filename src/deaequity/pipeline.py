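"""Three-stage pipeline: DEA on raw data -> SFA slack adjustment -> DEA re-run.

Stage 1 runs both the CCR (CRS) and BCC (VRS) envelopment models on one
period's cross-section.  Stage 2 regresses each input's total BCC slack on the
environment covariates and applies the Fried adjustment, raising inputs to a
common environment-and-luck baseline.  Stage 3 re-runs both models on the
adjusted inputs with the original outputs; any efficiency shift between stages
is then attributable to environment and noise, not management.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .dea import efficiency_table, solve_period
from .exceptions import DegenerateFrontierError
from .panel import PanelDataset
from .sfa import (
    adjust_inputs,
    build_slack_regressions,
    decompose_residuals,
    fit_frontier,
    sfa_table,
)

SCORE_COLUMNS = ["TE", "PTE", "SE"]


@dataclass
class PipelineReport:
    """All tables of one three-stage run, full precision."""

    period: object
    stage1: pd.DataFrame
    sfa: pd.DataFrame | None
    stage3: pd.DataFrame
    deltas: pd.DataFrame
    adjusted_inputs: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def run_three_stage(panel: PanelDataset, period=None, compute_se: bool = True) -> PipelineReport:
    """Run the full three-stage analysis on one period's cross-section.

    ``period`` defaults to the last period of the panel.  Degenerate stage-2
    regressions (an all-zero slack column, or every DMU efficient) degrade
    gracefully: the affected inputs pass through unadjusted and a warning is
    recorded; if every input is degenerate stage 3 equals stage 1.
    """
    if period is None:
        period = panel.periods[-1]
    if len(panel.dmus) < 2:
        raise ValueError("relative-efficiency analysis needs at least 2 DMUs")
    inputs, outputs = panel.period_data(period)

    stage1 = efficiency_table(inputs, outputs)
    warns: list[str] = []

    vrs_results = solve_period(inputs, outputs, rts="vrs")
    reg = build_slack_regressions(vrs_results, panel, period)

    fits, decomps = {}, {}
    for name in reg.slacks.columns:
        try:
            fit = fit_frontier(reg.slacks[name], reg.design, compute_se=compute_se)
        except DegenerateFrontierError:
            warns.append(f"input {name!r}: all stage-1 slacks zero; no adjustment applied")
            continue
        if not fit.converged:
            warns.append(f"input {name!r}: frontier MLE did not converge; "
                         "least-squares (gamma=0) fallback used")
        fits[name] = fit
        decomps[name] = decompose_residuals(fit, reg.slacks[name], reg.design)

    if fits:
        adjusted = adjust_inputs(inputs, fits, decomps, reg.design)
        stage3 = efficiency_table(adjusted, outputs)
        sfa_tab = sfa_table(fits)
    else:
        warns.append("stage 2 degenerate (all slacks zero): stage 3 equals stage 1")
        adjusted = inputs.copy()
        stage3 = stage1.copy()
        sfa_tab = None

    deltas = stage3[SCORE_COLUMNS] - stage1[SCORE_COLUMNS]
    return PipelineReport(
        period=period, stage1=stage1, sfa=sfa_tab, stage3=stage3, deltas=deltas,
        adjusted_inputs=adjusted, warnings=warns,
        metadata={"period": str(period), "n_dmus": len(panel.dmus),
                  "tool_version": __version__},
    )


def _rounded(frame: pd.DataFrame, digits: int) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(digits).map(lambda v: f"{v:.{digits}f}")
    return out


def write_report(report: PipelineReport, out_dir, digits: int = 3,
                 config_hash: str | None = None, seed=None) -> list[str]:
    """Write the display (rounded) and machine (full precision) CSVs plus metadata.

    Returns the list of files written.  Display rounding happens only here.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "stage1_efficiency": report.stage1,
        "stage3_efficiency": report.stage3,
        "stage_deltas": report.deltas,
        "adjusted_inputs": report.adjusted_inputs,
    }
    if report.sfa is not None:
        tables["sfa_regression"] = report.sfa
    for name, frame in tables.items():
        display = _rounded(frame, digits) if name != "sfa_regression" else frame
        display.to_csv(out / f"{name}.csv")
        frame.to_csv(out / f"{name}_full.csv", float_format="%.17g")
        written += [f"{name}.csv", f"{name}_full.csv"]
    meta = dict(report.metadata)
    meta.update({"seed": seed, "config_hash": config_hash, "warnings": report.warnings})
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    written.append("run_metadata.json")
    return written


def config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
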