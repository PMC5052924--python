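"""Structured run reports.

Pydantic models define the JSON report schema; every CLI run emits a
validated report.  The machine-readable schema itself is available via
:func:`report_json_schema`.
"""

from __future__ import annotations

from typing import Any, Optional

from pydantic import BaseModel, Field


class FitBlock(BaseModel):
    chi_square: float
    df: int
    p_value: float
    discrepancy: float
    per_group_discrepancy: list[float]
    converged: bool
    iterations: int
    n_total: int
    warnings: list[str] = Field(default_factory=list)
    estimates: dict[str, dict[str, float]]


class LadderStepBlock(BaseModel):
    step: str
    constraints_added: list[str]
    chi_square: float
    df: int
    p_value: float
    delta_chi_square: float
    delta_df: int
    delta_p: float


class ProbeBlock(BaseModel):
    verdict: str
    alpha: float
    base: dict[str, float]
    augmented: dict[str, float]
    new_moment_residuals_gt_threshold: int
    new_moment_cells: int
    aux_direct_mis_gt_threshold: int
    aux_direct_candidates: int
    top_modification_indices: list[dict[str, Any]]


class RunReport(BaseModel):
    """Top-level report written by every CLI run."""

    tool: str = "mgsem"
    version: str
    subcommand: str
    seed: Optional[int] = None
    config: dict[str, Any] = Field(default_factory=dict)
    headline: str
    fit: Optional[FitBlock] = None
    ladder: Optional[list[LadderStepBlock]] = None
    probe: Optional[ProbeBlock] = None
    diagnostics: Optional[dict[str, Any]] = None
    indices: Optional[dict[str, float]] = None
    files: Optional[dict[str, dict[str, str]]] = None


def report_json_schema() -> dict:
    """JSON Schema for the run report."""
    return RunReport.model_json_schema()
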