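"""Localizing model-data inconsistency.

The chi-square test says *whether* the model is inconsistent with the
data; the tools here say *where*: a severity heuristic on the chi-square
scale, score-test modification indices (the expected chi-square drop
from freeing one fixed cell) with expected parameter changes, and
normalized covariance residuals with threshold screens.

The toolkit reports diagnostics; it never frees parameters on its own —
chasing modification indices cannot fix a wrong number of latents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .estimator import (
    FitResult,
    _group_discrepancy,
    delta_matrices,
    expected_information,
    implied_moments,
)
from .model_spec import SINGLE_INDICATOR

__all__ = ["severity", "modification_indices", "normalized_residuals",
           "screen", "diagnose", "DiagnosticsReport", "MIRecord"]

logger = logging.getLogger(__name__)

MI_THRESHOLD = 4.0
RESID_THRESHOLD = 2.0


def severity(T: float, df: int) -> tuple[float, float]:
    """Chi-square severity: z = (T - df)/sqrt(2 df) and the exact tail p.

    A chi-square with many degrees of freedom is nearly normal with
    mean df and variance 2 df, so z counts the standard deviations by
    which the statistic exceeds its expectation under a correct model.
    The p-value is the exact chi-square upper tail, not the normal
    approximation.
    """
    if T < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    if df < 1:
        raise ValueError("severity is undefined at df = 0")
    z = (T - df) / np.sqrt(2.0 * df)
    return float(z), float(stats.chi2.sf(T, df))


@dataclass(frozen=True)
class MIRecord:
    group: str
    matrix: str
    row: str  # indicator (lambda/theta row)
    col: str  # latent, or second indicator for theta
    mi: float
    epc: float

    @property
    def address(self) -> tuple[str, str, str, str]:
        return (self.matrix, self.row, self.col, self.group)


def _candidate_cells(fit: FitResult, candidates: str) -> list[tuple[int, str, int, int]]:
    spec = fit.spec
    observed = {v: i for i, v in enumerate(spec.observed_variables)}
    latent = {v: i for i, v in enumerate(spec.latent_names)}
    owner = {a.indicator_name: l.name for l in spec.latents for a in l.indicators}
    aux_names = {l.name for l in spec.auxiliary_latents}
    common_inds = [
        a.indicator_name for l in spec.common_factors for a in l.indicators
    ]
    # cells already governed by the model (free or fixed) are not candidates
    taken: set[tuple[int, str, int, int]] = set(
        (gi, kind, i, j) for fp in fit.param_table.free for gi, kind, i, j in fp.addresses
    )
    taken.update((gi, kind, i, j) for gi, kind, i, j, _ in fit.param_table.fixed)

    want_cross = candidates in ("cross_loadings", "all")
    want_aux = candidates in ("direct_aux_effects", "all")
    want_theta = candidates in ("error_covariances", "all")
    out: list[tuple[int, str, int, int]] = []
    for gi in range(len(spec.groups)):
        if want_cross:
            for y in common_inds:
                for l in spec.common_factors:
                    if owner[y] == l.name:
                        continue
                    cell = (gi, "lambda", observed[y], latent[l.name])
                    if cell not in taken:
                        out.append(cell)
        if want_aux:
            for y in common_inds:
                for name in aux_names:
                    cell = (gi, "lambda", observed[y], latent[name])
                    if cell not in taken:
                        out.append(cell)
        if want_theta:
            for a in range(len(common_inds)):
                for b in range(a + 1, len(common_inds)):
                    cell = (gi, "theta", observed[common_inds[a]], observed[common_inds[b]])
                    if cell not in taken and (cell[0], cell[1], cell[3], cell[2]) not in taken:
                        out.append(cell)
    return out


def modification_indices(
    fit: FitResult, candidates: str = "all"
) -> list[MIRecord]:
    """Score-test (1-df) statistics for freeing fixed cells, sorted descending.

    For each candidate the statistic is the expected chi-square drop
    were that single cell freed, with the information of the free
    parameters partialled out; the expected parameter change (EPC)
    accompanies it.  Candidate classes: ``cross_loadings``,
    ``direct_aux_effects``, ``error_covariances``, or ``all``.
    """
    if not fit.converged:
        raise ValueError("modification indices require a converged fit")
    spec = fit.spec
    cells = _candidate_cells(fit, candidates)
    if not cells:
        return []
    q = fit.param_table.q
    use_means = spec.mean_structure
    n_total = fit.n_total

    # gradient of F at the solution for each candidate cell
    grads = np.zeros(len(cells))
    for gi, (g, mat) in enumerate(zip(fit.data, fit.matrices)):
        sigma, mu = implied_moments(mat)
        sign, logdet_S = np.linalg.slogdet(g.cov)
        _, G, u = _group_discrepancy(
            g.cov, logdet_S, sigma, g.means if use_means else None, mu
        )
        w = g.n / n_total
        for k, (gj, kind, i, j) in enumerate(cells):
            if gj != gi:
                continue
            dS, dmu = delta_matrices(mat, (kind, i, j), use_means)
            val = float(np.sum(G * dS))
            if dmu is not None and u is not None:
                val += -2.0 * float(u @ dmu)
            grads[k] = w * val

    H = expected_information(spec, fit.data, fit.param_table, fit.matrices, extra=cells)
    Hff = H[:q, :q]
    out: list[MIRecord] = []
    obs = spec.observed_variables
    lats = spec.latent_names
    try:
        cho = linalg.cho_factor(Hff) if q else None
    except linalg.LinAlgError:
        cho = None
        logger.warning("free-parameter information singular; MIs not partialled")
    for k, (gi, kind, i, j) in enumerate(cells):
        a = q + k
        h_aa = H[a, a]
        if q and cho is not None:
            h_af = H[a, :q]
            h_tilde = h_aa - float(h_af @ linalg.cho_solve(cho, h_af))
        else:
            h_tilde = h_aa
        if h_tilde <= 1e-12:
            logger.warning("singular information for candidate %s; skipped", (kind, i, j))
            continue
        mi = 0.5 * fit.multiplier * grads[k] ** 2 / h_tilde
        epc = -grads[k] / h_tilde
        col = lats[j] if kind == "lambda" else obs[j]
        out.append(
            MIRecord(
                group=spec.groups[gi], matrix=kind, row=obs[i], col=col,
                mi=float(max(mi, 0.0)), epc=float(epc),
            )
        )
    out.sort(key=lambda r: -r.mi)
    return out


def normalized_residuals(fit: FitResult) -> dict[str, np.ndarray]:
    """Per-group normalized covariance residuals.

    Entry (i, j) is (s_ij - sigma_ij) / sqrt((sigma_ii sigma_jj +
    sigma_ij^2) / N_g); approximately unit-variance under a correct
    model, so entries beyond +/-2 flag local misfit.
    """
    out: dict[str, np.ndarray] = {}
    for g, mat in zip(fit.data, fit.matrices):
        sigma, _ = implied_moments(mat)
        denom = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / g.n)
        out[g.label] = (g.cov - sigma) / denom
    return out


@dataclass
class DiagnosticsReport:
    """Bundled misfit diagnostics for one fitted model."""

    severity_z: float
    p_value: float
    chi_square: float
    df: int
    mod_indices: list[MIRecord]
    residuals: dict[str, np.ndarray]
    mi_threshold: float = MI_THRESHOLD
    resid_threshold: float = RESID_THRESHOLD
    counts: dict[str, int] = field(default_factory=dict)
    variable_names: tuple[str, ...] = ()
    spec: object = None

    def top_suspects(self, k: int = 10) -> str:
        lines = [f"{'group':<8} {'cell':<28} {'MI':>8} {'EPC':>8}"]
        for r in self.mod_indices[:k]:
            cell = f"{r.matrix}[{r.row},{r.col}]"
            lines.append(f"{r.group:<8} {cell:<28} {r.mi:8.2f} {r.epc:8.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "severity_z": self.severity_z,
            "p_value": self.p_value,
            "thresholds": {"mi": self.mi_threshold, "residual": self.resid_threshold},
            "counts": dict(self.counts),
            "modification_indices": [
                {"group": r.group, "matrix": r.matrix, "row": r.row, "col": r.col,
                 "mi": r.mi, "epc": r.epc}
                for r in self.mod_indices
            ],
            "residuals": {k: v.tolist() for k, v in self.residuals.items()},
        }


def diagnose(
    fit: FitResult,
    candidates: str = "all",
    mi_threshold: float = MI_THRESHOLD,
    resid_threshold: float = RESID_THRESHOLD,
) -> DiagnosticsReport:
    """Assemble the full diagnostics report for a converged fit."""
    z, p = severity(fit.chi_square, fit.df) if fit.df >= 1 else (float("nan"), 1.0)
    mis = modification_indices(fit, candidates)
    resid = normalized_residuals(fit)
    report = DiagnosticsReport(
        severity_z=z, p_value=p, chi_square=fit.chi_square, df=fit.df,
        mod_indices=mis, residuals=resid,
        mi_threshold=mi_threshold, resid_threshold=resid_threshold,
        variable_names=tuple(fit.spec.observed_variables),
        spec=fit.spec,
    )
    n_resid = 0
    for g, mat in resid.items():
        iu = np.triu_indices_from(mat)
        n_resid += int(np.sum(np.abs(mat[iu]) > resid_threshold))
    report.counts = {
        "mi_exceed": sum(r.mi > mi_threshold for r in mis),
        "resid_exceed": n_resid,
        "candidates": len(mis),
    }
    return report


def descriptive_fit_indices(fit: FitResult) -> dict[str, float]:
    """RMSEA and CFI, offered as descriptive summaries only.

    These indices never constitute acceptance evidence here: closeness
    of fit cannot certify that the model's causal structure matches the
    data-generating structure.  The chi-square test and its exact p
    remain the decision statistics.
    """
    G = len(fit.data)
    n = fit.multiplier
    T, df = fit.chi_square, fit.df
    rmsea = float(np.sqrt(G * max(T - df, 0.0) / (df * n))) if df > 0 else float("nan")
    # independence baseline: free variances (and means) only
    F_b = 0.0
    n_total = sum(g.n for g in fit.data)
    p = len(fit.spec.observed_variables)
    for g in fit.data:
        _, logdet_S = np.linalg.slogdet(g.cov)
        F_b += (g.n / n_total) * (float(np.sum(np.log(np.diag(g.cov)))) - logdet_S)
    T_b = n * F_b
    df_b = G * p * (p - 1) // 2
    denom = max(T_b - df_b, 1e-12)
    cfi = float(1.0 - max(T - df, 0.0) / max(denom, max(T - df, 0.0), 1e-12))
    return {"rmsea": rmsea, "cfi": cfi, "baseline_chi_square": float(T_b),
            "baseline_df": df_b}


def screen(
    report: DiagnosticsReport,
    block: str,
    spec=None,
) -> dict[str, int]:
    """Count threshold exceedances restricted to a named parameter block.

    Blocks: ``aux_direct`` (cause-to-indicator loadings plus the
    cause/indicator residual rows), ``cross_loadings``,
    ``error_covariances``, ``all``.
    """
    known = ("aux_direct", "cross_loadings", "error_covariances", "all")
    if block not in known:
        raise ValueError(f"unknown block {block!r}; expected one of {known}")

    spec = spec if spec is not None else report.spec
    if spec is not None:
        aux_inds = {a.indicator_name for l in spec.auxiliary_latents for a in l.indicators}
        aux_lats = {l.name for l in spec.auxiliary_latents}
        common_inds = {a.indicator_name for l in spec.common_factors for a in l.indicators}
    else:
        aux_inds, aux_lats, common_inds = set(), set(), set()

    def in_block(r: MIRecord) -> bool:
        if block == "all":
            return True
        if block == "aux_direct":
            return r.matrix == "lambda" and r.col in aux_lats
        if block == "cross_loadings":
            return r.matrix == "lambda" and r.col not in aux_lats
        return r.matrix == "theta"

    mis = [r for r in report.mod_indices if in_block(r)]
    out = {
        "candidates": len(mis),
        "mi_exceed": sum(r.mi > report.mi_threshold for r in mis),
    }
    # residual screen over the matching covariance block
    names = list(report.variable_names)
    n_exceed = 0
    n_cells = 0
    for gmat in report.residuals.values():
        for a in range(len(names)):
            for b in range(a, len(names)):
                va, vb = names[a], names[b]
                if block == "all":
                    pass
                elif block == "aux_direct":
                    if not (
                        (va in aux_inds and vb in common_inds)
                        or (vb in aux_inds and va in common_inds)
                    ):
                        continue
                else:
                    if va in aux_inds or vb in aux_inds:
                        continue
                n_cells += 1
                if abs(gmat[a, b]) > report.resid_threshold:
                    n_exceed += 1
    out["resid_cells"] = n_cells
    out["resid_exceed"] = n_exceed
    return out
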