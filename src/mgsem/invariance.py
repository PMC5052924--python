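"""The invariance assessment strategy.

Order of business, honoring the chi-square-first testing philosophy:

1. Test the configural model rigorously (exact chi-square p, severity z).
2. Probe its validity with auxiliary observed causes (e.g. Sex, Age)
   entered as correlated single-indicator exogenous latents influencing
   every common factor: if the factors are the true causal foundations
   of the indicators, they must be able to route the auxiliary causes'
   influence to the indicators.
3. Climb the constrained ladder (metric -> scalar -> strict), testing
   each step by a nested chi-square difference.

A failing configural test is never suppressed: invariant estimates of a
misspecified model are invariant misrepresentations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .data_io import GroupMoments
from .diagnostics import diagnose, modification_indices, screen
from .estimator import FitResult, fit, to_all_eta
from .model_spec import (
    COMMON_FACTOR,
    SINGLE_INDICATOR,
    IndicatorAssignment,
    LatentSpec,
    ModelSpecError,
    ModelSpecification,
    PathSpec,
    enumerate_parameters,
)

__all__ = ["LadderStep", "ProbeResult", "add_auxiliary_causes", "run_probe",
           "run_ladder", "chi_square_difference", "NestingError"]

logger = logging.getLogger(__name__)

_STEP_CLASSES = {
    "configural": (),
    "metric": ("loadings",),
    "scalar": ("intercepts",),
    "strict": ("residuals",),
}


class NestingError(ValueError):
    """Raised when a chi-square difference is requested for non-nested models."""


def add_auxiliary_causes(
    spec: ModelSpecification,
    aux: Sequence[str],
    error_proportion: float = 0.02,
) -> ModelSpecification:
    """Add observed causes as correlated single-indicator exogenous latents.

    Each auxiliary variable becomes a latent with a single indicator
    (loading fixed at 1.0, measurement error variance fixed at
    ``error_proportion`` times the indicator's sample variance in each
    group) and a path to every common factor.  The auxiliary latents
    covary with one another; the common factors' disturbances remain
    mutually correlated.
    """
    if not aux:
        return spec
    existing = set(spec.observed_variables)
    for name in aux:
        if name in existing:
            raise ModelSpecError(
                f"auxiliary variable {name!r} is already an indicator in the model"
            )
    if len(set(aux)) != len(aux):
        raise ModelSpecError("duplicate auxiliary variable names")
    new_latents = list(spec.latents)
    new_paths = list(spec.paths)
    for name in aux:
        new_latents.append(
            LatentSpec(
                name, SINGLE_INDICATOR,
                (IndicatorAssignment(name, name, is_scaling=True),),
                fixed_error_proportion=error_proportion,
            )
        )
        for factor in spec.common_factors:
            new_paths.append(PathSpec(cause=name, effect=factor.name))
    out = replace(spec, latents=tuple(new_latents), paths=tuple(new_paths))
    return out.validate()


@dataclass
class ProbeResult:
    """Outcome of the auxiliary-cause validity probe."""

    base: FitResult
    augmented: FitResult
    new_moment_residual_count: int
    new_moment_cells: int
    aux_direct_mi_count: int
    aux_direct_candidates: int
    top_mis: list
    verdict: str  # no_evidence_against / evidence_of_misspecification / indeterminate
    alpha: float

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "alpha": self.alpha,
            "base": {"chi_square": self.base.chi_square, "df": self.base.df,
                     "p_value": self.base.p_value},
            "augmented": {"chi_square": self.augmented.chi_square,
                          "df": self.augmented.df, "p_value": self.augmented.p_value},
            "new_moment_residuals_gt_threshold": self.new_moment_residual_count,
            "new_moment_cells": self.new_moment_cells,
            "aux_direct_mis_gt_threshold": self.aux_direct_mi_count,
            "aux_direct_candidates": self.aux_direct_candidates,
            "top_modification_indices": [
                {"group": r.group, "matrix": r.matrix, "row": r.row,
                 "col": r.col, "mi": r.mi, "epc": r.epc}
                for r in self.top_mis
            ],
        }


def run_probe(
    spec: ModelSpecification,
    data: Sequence[GroupMoments],
    aux: Sequence[str],
    alpha: float = 0.05,
    error_proportion: float = 0.02,
    top_k: int = 10,
) -> ProbeResult:
    """Fit base and auxiliary-augmented models and assemble the verdict.

    Misspecification is flagged when either chi-square test rejects at
    ``alpha``; diagnostics are restricted to the new moments (auxiliary
    by indicator covariances) and the candidate direct auxiliary-cause
    loadings exposed by the all-eta form.
    """
    for name in aux:
        for g in data:
            if name not in g.variable_names:
                raise ModelSpecError(
                    f"auxiliary variable {name!r} absent from group {g.label!r} data"
                )
    base_fit = fit(spec, data)
    aug_spec = to_all_eta(add_auxiliary_causes(spec, aux, error_proportion))
    aug_fit = fit(aug_spec, data)

    if not (base_fit.converged and aug_fit.converged):
        verdict = "indeterminate"
        logger.warning("probe fits did not converge; verdict is indeterminate")
    elif base_fit.p_value < alpha or aug_fit.p_value < alpha:
        verdict = "evidence_of_misspecification"
    else:
        verdict = "no_evidence_against"

    report = diagnose(aug_fit, candidates="direct_aux_effects")
    blk = screen(report, "aux_direct")
    aux_mis = [r for r in report.mod_indices]
    return ProbeResult(
        base=base_fit, augmented=aug_fit,
        new_moment_residual_count=blk["resid_exceed"],
        new_moment_cells=blk["resid_cells"],
        aux_direct_mi_count=blk["mi_exceed"],
        aux_direct_candidates=blk["candidates"],
        top_mis=aux_mis[:top_k],
        verdict=verdict, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# nested difference testing


def _partition(spec: ModelSpecification) -> tuple[set, dict]:
    """Free-cell set and equality-class map, keyed by name-based addresses."""
    free: set = set()
    classes: dict = {}
    for p in enumerate_parameters(spec):
        key = (p.address.matrix, p.address.row, p.address.col, p.address.group)
        if p.status == "free":
            free.add(key)
            classes[key] = p.label if p.label is not None else key
    return free, classes


def assert_nested(
    restricted: ModelSpecification, full: ModelSpecification
) -> None:
    """Structurally verify that ``restricted`` is nested in ``full``.

    Every cell free in the restricted model must be free in the full
    model (latent means freed alongside intercept constraints are the
    one sanctioned exception, being part of the scalar-step
    reparameterization), and cells equal in the full model must remain
    equal in the restricted one.
    """
    if restricted.groups != full.groups:
        raise NestingError("models declare different groups")
    if restricted.observed_variables != full.observed_variables:
        raise NestingError("models cover different observed variables")
    free_r, cls_r = _partition(restricted)
    free_f, cls_f = _partition(full)
    extra = {k for k in free_r - free_f if k[0] != "alpha"}
    if extra:
        raise NestingError(
            f"restricted model frees cells the full model fixes: {sorted(extra)[:4]}"
        )
    # partition refinement on shared free cells
    from collections import defaultdict

    groups_f = defaultdict(list)
    for key in free_f & free_r:
        groups_f[cls_f[key]].append(key)
    for label, members in groups_f.items():
        if len(members) < 2:
            continue
        labels_r = {cls_r[k] for k in members}
        if len(labels_r) != 1:
            raise NestingError(
                f"cells constrained equal in the full model are unconstrained in the "
                f"restricted one: {members[:4]}"
            )


def chi_square_difference(
    restricted: FitResult, full: FitResult, tol: float = 1e-6
) -> tuple[float, int, float]:
    """Nested chi-square difference test.

    Returns (delta_T, delta_df, p).  delta_T below zero beyond the
    tolerance is clipped at 0 with a warning; delta_df = 0 yields p = 1
    by convention.
    """
    assert_nested(restricted.spec, full.spec)
    delta_df = restricted.df - full.df
    if delta_df < 0:
        raise NestingError(
            f"restricted model has fewer df ({restricted.df}) than the full model ({full.df})"
        )
    delta_T = restricted.chi_square - full.chi_square
    if delta_T < -tol * max(1.0, full.chi_square):
        logger.warning(
            "chi-square difference negative (%.4g); clipped at 0 — check convergence",
            delta_T,
        )
    delta_T = max(delta_T, 0.0)
    p = float(stats.chi2.sf(delta_T, delta_df)) if delta_df > 0 else 1.0
    return float(delta_T), int(delta_df), p


@dataclass
class LadderStep:
    """One rung of the constrained invariance ladder."""

    name: str
    constraints_added: tuple[str, ...]
    fit: FitResult
    delta_T: float
    delta_df: int
    delta_p: float

    def to_dict(self) -> dict:
        return {
            "step": self.name,
            "constraints_added": list(self.constraints_added),
            "chi_square": self.fit.chi_square,
            "df": self.fit.df,
            "p_value": self.fit.p_value,
            "delta_chi_square": self.delta_T,
            "delta_df": self.delta_df,
            "delta_p": self.delta_p,
        }


def run_ladder(
    spec: ModelSpecification,
    data: Sequence[GroupMoments],
    steps: Sequence[Union[str, tuple[str, Sequence[str]]]] = (
        "configural", "metric", "scalar", "strict",
    ),
) -> list[LadderStep]:
    """Run the progressively constrained invariance ladder.

    Each step refits with the accumulated between-group constraint
    classes and reports the nested chi-square difference against the
    previous rung.  The configural step comes first; the scalar step
    requires a mean structure and mean-bearing data.
    """
    steps = list(steps)
    if not steps or steps[0] != "configural":
        raise ModelSpecError("the ladder must start with the configural step")
    out: list[LadderStep] = []
    accumulated: tuple[str, ...] = ()
    prev: Optional[FitResult] = None
    for step in steps:
        if isinstance(step, str):
            name, classes = step, _STEP_CLASSES.get(step)
            if classes is None:
                raise ModelSpecError(f"unknown ladder step {step!r}")
        else:
            name, classes = step[0], tuple(step[1])
        if "intercepts" in classes:
            if not spec.mean_structure:
                raise ModelSpecError(
                    "the scalar step requires a mean structure in the model"
                )
            if any(g.means is None for g in data):
                raise ModelSpecError("the scalar step requires mean-bearing data")
        new = tuple(c for c in classes if c not in accumulated)
        accumulated = accumulated + new
        step_spec = replace(
            spec, group_equal=tuple(dict.fromkeys(spec.group_equal + accumulated))
        )
        step_fit = fit(step_spec, data)
        if prev is None:
            out.append(LadderStep(name, new, step_fit, 0.0, 0, 1.0))
        else:
            dT, ddf, p = chi_square_difference(step_fit, prev)
            out.append(LadderStep(name, new, step_fit, dT, ddf, p))
        prev = step_fit
    return out
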