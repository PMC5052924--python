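"""Normal-theory maximum-likelihood estimation for multi-group models.

The model is held in all-eta form per group:

    Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta
    mu    = tau + Lambda (I-B)^-1 alpha

The discrepancy minimized is the classical multi-group ML fit function

    F = sum_g (N_g / N) [ ln|Sigma_g| + tr(S_g Sigma_g^-1) - ln|S_g| - p
                          + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

and the test statistic is T = (N - G) * F at the minimizer (the
LISREL-era convention; ``chi2_multiplier="group"`` reports
T = sum_g (N_g - 1) F_g instead).  Optimization is quasi-Newton with
analytic gradients, followed by Fisher-scoring polish; standard errors
come from the inverse expected information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .data_io import GroupMoments, align_to_model
from .model_spec import (
    FIXED,
    FIXED_PROPORTIONAL,
    FREE,
    ModelSpecError,
    ModelSpecification,
    ParamAddress,
    Parameter,
    degrees_of_freedom,
    enumerate_parameters,
)

__all__ = ["ModelMatrices", "FitResult", "implied_moments", "ml_discrepancy",
           "fit", "to_all_eta", "EstimationError"]

logger = logging.getLogger(__name__)

_BIG = 1e10  # barrier value when the implied covariance loses positive definiteness


class EstimationError(RuntimeError):
    """Raised for structural problems that preclude estimation."""


@dataclass
class ModelMatrices:
    """Numeric coefficient matrices for one group (all-eta form)."""

    observed: tuple[str, ...]
    latent: tuple[str, ...]
    lam: np.ndarray            # p x m loadings
    beta: np.ndarray           # m x m latent paths
    psi: np.ndarray            # m x m latent / disturbance covariances
    theta: np.ndarray          # p x p measurement error covariances
    tau: Optional[np.ndarray] = None   # p intercepts
    alpha: Optional[np.ndarray] = None  # m latent means

    def copy(self) -> "ModelMatrices":
        return ModelMatrices(
            self.observed, self.latent,
            self.lam.copy(), self.beta.copy(), self.psi.copy(), self.theta.copy(),
            None if self.tau is None else self.tau.copy(),
            None if self.alpha is None else self.alpha.copy(),
        )


def implied_moments(mat: ModelMatrices) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Model-implied covariance matrix (and mean vector when present)."""
    m = len(mat.latent)
    imb = np.eye(m) - mat.beta
    try:
        A = np.linalg.inv(imb)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular (I - B): latent system has no reduced form") from exc
    omega = A @ mat.psi @ A.T
    sigma = mat.lam @ omega @ mat.lam.T + mat.theta
    sigma = 0.5 * (sigma + sigma.T)
    mu = None
    if mat.tau is not None:
        alpha = mat.alpha if mat.alpha is not None else np.zeros(m)
        mu = mat.tau + mat.lam @ (A @ alpha)
    return sigma, mu


def _group_discrepancy(
    S: np.ndarray,
    logdet_S: float,
    sigma: np.ndarray,
    xbar: Optional[np.ndarray],
    mu: Optional[np.ndarray],
) -> tuple[float, np.ndarray, Optional[np.ndarray]]:
    """F_g plus dF/dSigma and the weighted residual mean (for gradients)."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance not positive definite")
    c, low = None, None
    isig = np.linalg.inv(sigma)
    val = logdet + float(np.sum(isig * S)) - logdet_S - p
    G = isig - isig @ S @ isig
    u = None
    if xbar is not None and mu is not None:
        d = xbar - mu
        u = isig @ d
        val += float(d @ u)
        G = G - np.outer(u, u)
    return val, G, u


def ml_discrepancy(
    moments: Sequence[GroupMoments],
    implied: Sequence[tuple[np.ndarray, Optional[np.ndarray]]],
) -> float:
    """Weighted multi-group ML discrepancy between sample and implied moments."""
    n_total = sum(g.n for g in moments)
    F = 0.0
    for g, (sigma, mu) in zip(moments, implied):
        sign, logdet_S = np.linalg.slogdet(g.cov)
        if sign <= 0:
            raise EstimationError(f"group {g.label!r}: sample covariance not positive definite")
        xbar = g.means if mu is not None else None
        val, _, _ = _group_discrepancy(g.cov, logdet_S, sigma, xbar, mu)
        F += (g.n / n_total) * val
    if F < 0 and F > -1e-10:
        F = 0.0
    return F


# ---------------------------------------------------------------------------
# parameter table


@dataclass
class _FreeParam:
    name: str
    start: float
    addresses: list[tuple[int, str, int, int]]  # (group index, matrix, i, j)


@dataclass
class ParamTable:
    free: list[_FreeParam]
    fixed: list[tuple[int, str, int, int, float]]

    @property
    def q(self) -> int:
        return len(self.free)


def _address_indices(
    addr: ParamAddress, observed: dict[str, int], latent: dict[str, int]
) -> tuple[str, int, int]:
    mat = addr.matrix
    if mat == "lambda":
        return mat, observed[addr.row], latent[addr.col]
    if mat == "beta" or mat == "psi":
        return mat, latent[addr.row], latent[addr.col]
    if mat == "theta":
        return mat, observed[addr.row], observed[addr.col]
    if mat == "tau":
        return mat, observed[addr.row], 0
    if mat == "alpha":
        return mat, latent[addr.row], 0
    raise ModelSpecError(f"unknown matrix {mat!r}")


def _start_value(
    addr: ParamAddress, spec: ModelSpecification, data: Sequence[GroupMoments],
    gi: int, observed: dict[str, int],
) -> float:
    S = data[gi].cov
    if addr.matrix == "lambda":
        return 1.0
    if addr.matrix == "theta":
        return 0.5 * S[observed[addr.row], observed[addr.row]]
    if addr.matrix == "psi":
        if addr.row != addr.col:
            return 0.0
        latent = spec.latent(addr.row)
        scal = next(a for a in latent.indicators if a.is_scaling)
        j = observed[scal.indicator_name]
        if latent.kind == "single_indicator_exogenous":
            return (1.0 - (latent.fixed_error_proportion or 0.0)) * S[j, j]
        return 0.5 * S[j, j]
    if addr.matrix == "beta":
        return 0.0
    if addr.matrix == "tau":
        means = data[gi].means
        return 0.0 if means is None else float(means[observed[addr.row]])
    return 0.0  # alpha


def build_param_table(
    spec: ModelSpecification, data: Sequence[GroupMoments]
) -> ParamTable:
    """Resolve spec parameters against data into a flat free-parameter table.

    Proportional fixed values (auxiliary measurement error variances)
    are resolved to ``proportion x sample variance`` per group here.
    """
    observed = {v: i for i, v in enumerate(spec.observed_variables)}
    latent = {v: i for i, v in enumerate(spec.latent_names)}
    gidx = {g: i for i, g in enumerate(spec.groups)}
    params = enumerate_parameters(spec)

    free: dict[str, _FreeParam] = {}
    fixed: list[tuple[int, str, int, int, float]] = []
    order: list[str] = []
    for k, par in enumerate(params):
        gi = gidx[par.address.group]
        mat, i, j = _address_indices(par.address, observed, latent)
        if par.status == FIXED:
            fixed.append((gi, mat, i, j, float(par.value)))
            continue
        if par.status == FIXED_PROPORTIONAL:
            S = data[gi].cov
            fixed.append((gi, mat, i, j, float(par.value) * S[i, i]))
            continue
        name = par.label or f"{mat}[{par.address.row},{par.address.col or '-'}]@{par.address.group}"
        start = _start_value(par.address, spec, data, gi, observed)
        if name in free:
            fp = free[name]
            fp.addresses.append((gi, mat, i, j))
            fp.start = 0.5 * (fp.start + start)
        else:
            free[name] = _FreeParam(name, start, [(gi, mat, i, j)])
            order.append(name)
    return ParamTable([free[n] for n in order], fixed)


def build_matrices(
    spec: ModelSpecification, data: Sequence[GroupMoments], table: ParamTable,
    x: Optional[np.ndarray] = None,
) -> list[ModelMatrices]:
    """Materialize per-group coefficient matrices at parameter vector ``x``."""
    p = len(spec.observed_variables)
    m = len(spec.latents)
    obs = tuple(spec.observed_variables)
    lat = tuple(spec.latent_names)
    mats = []
    for _ in spec.groups:
        mats.append(
            ModelMatrices(
                obs, lat,
                np.zeros((p, m)), np.zeros((m, m)), np.zeros((m, m)), np.zeros((p, p)),
                np.zeros(p) if spec.mean_structure else None,
                np.zeros(m) if spec.mean_structure else None,
            )
        )
    for gi, mat, i, j, val in table.fixed:
        _set_cell(mats[gi], mat, i, j, val)
    if x is None:
        x = np.array([fp.start for fp in table.free])
    for fp, val in zip(table.free, x):
        for gi, mat, i, j in fp.addresses:
            _set_cell(mats[gi], mat, i, j, val)
    return mats


def _set_cell(m: ModelMatrices, mat: str, i: int, j: int, val: float) -> None:
    if mat == "lambda":
        m.lam[i, j] = val
    elif mat == "beta":
        m.beta[i, j] = val
    elif mat == "psi":
        m.psi[i, j] = val
        m.psi[j, i] = val
    elif mat == "theta":
        m.theta[i, j] = val
        m.theta[j, i] = val
    elif mat == "tau":
        m.tau[i] = val
    elif mat == "alpha":
        m.alpha[i] = val


# ---------------------------------------------------------------------------
# objective and gradient


class _Objective:
    def __init__(self, spec, data, table):
        self.spec = spec
        self.data = data
        self.table = table
        self.n_total = sum(g.n for g in data)
        self.weights = [g.n / self.n_total for g in data]
        self.logdet_S = []
        for g in data:
            sign, ld = np.linalg.slogdet(g.cov)
            if sign <= 0:
                raise EstimationError(
                    f"group {g.label!r}: sample covariance not positive definite"
                )
            self.logdet_S.append(ld)
        self.use_means = spec.mean_structure
        if self.use_means and any(g.means is None for g in data):
            raise EstimationError("mean structure requested but data lack mean vectors")

    def value_grad(self, x: np.ndarray) -> tuple[float, np.ndarray, Optional[list[float]]]:
        mats = build_matrices(self.spec, self.data, self.table, x)
        q = self.table.q
        grad = np.zeros(q)
        F = 0.0
        per_group: list[float] = []
        group_arrays = []
        for gi, (g, mat) in enumerate(zip(self.data, mats)):
            m = len(mat.latent)
            A = np.linalg.inv(np.eye(m) - mat.beta)
            omega = A @ mat.psi @ A.T
            sigma = mat.lam @ omega @ mat.lam.T + mat.theta
            sigma = 0.5 * (sigma + sigma.T)
            mu = None
            if self.use_means:
                mu = mat.tau + mat.lam @ (A @ mat.alpha)
            try:
                val, G, u = _group_discrepancy(
                    g.cov, self.logdet_S[gi], sigma,
                    g.means if self.use_means else None, mu,
                )
            except np.linalg.LinAlgError:
                return _BIG, np.zeros(q), None
            per_group.append(val)
            F += self.weights[gi] * val
            group_arrays.append((A, omega, G, u, mat))

        # gradients: dense per-matrix derivative arrays, then gather
        per_mat = []
        for gi, (A, omega, G, u, mat) in enumerate(group_arrays):
            lam_omega = mat.lam @ omega
            g_lam = 2.0 * G @ lam_omega
            K = mat.lam.T @ G @ mat.lam
            M = A.T @ K @ A
            g_beta = 2.0 * A.T @ K @ omega
            g_tau = g_alpha = None
            if self.use_means and u is not None:
                a_alpha = A @ mat.alpha
                lt_u = mat.lam.T @ u
                g_lam = g_lam - 2.0 * np.outer(u, a_alpha)
                g_beta = g_beta - 2.0 * np.outer(A.T @ lt_u, a_alpha)
                g_tau = -2.0 * u
                g_alpha = -2.0 * A.T @ lt_u
            per_mat.append({"lambda": g_lam, "beta": g_beta, "psi": M,
                            "theta": G, "tau": g_tau, "alpha": g_alpha})

        for k, fp in enumerate(self.table.free):
            acc = 0.0
            for gi, mat, i, j in fp.addresses:
                arr = per_mat[gi][mat]
                if mat in ("psi", "theta"):
                    acc += self.weights[gi] * (arr[i, i] if i == j else 2.0 * arr[i, j])
                elif mat in ("tau", "alpha"):
                    acc += self.weights[gi] * arr[i]
                else:
                    acc += self.weights[gi] * arr[i, j]
            grad[k] = acc
        return F, grad, per_group


def delta_matrices(
    mat: ModelMatrices, address: tuple[str, int, int], use_means: bool
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """(dSigma/dtheta, dmu/dtheta) for a unit change of one matrix cell."""
    p, m = mat.lam.shape
    kind, i, j = address
    A = np.linalg.inv(np.eye(m) - mat.beta)
    L = mat.lam @ A
    omega = A @ mat.psi @ A.T
    dmu = None
    a_alpha = A @ mat.alpha if (use_means and mat.alpha is not None) else None
    if kind == "lambda":
        v = (mat.lam @ omega)[:, j]
        dS = np.zeros((p, p))
        dS[i, :] += v
        dS[:, i] += v
        if use_means:
            dmu = np.zeros(p)
            dmu[i] = a_alpha[j]
        return dS, dmu
    if kind == "theta":
        dS = np.zeros((p, p))
        dS[i, j] += 1.0
        dS[j, i] += 1.0
        if i == j:
            dS[i, i] = 1.0
        return dS, None
    if kind == "psi":
        li, lj = L[:, i], L[:, j]
        dS = np.outer(li, lj)
        dS = dS + dS.T if i != j else np.outer(li, li)
        return dS, None
    if kind == "beta":
        w = (omega @ mat.lam.T)[j, :]
        dS = np.outer(L[:, i], w)
        dS = dS + dS.T
        if use_means:
            dmu = a_alpha[j] * L[:, i]
        return dS, dmu
    if kind == "tau":
        dmu = np.zeros(p)
        dmu[i] = 1.0
        return np.zeros((p, p)), dmu
    if kind == "alpha":
        return np.zeros((p, p)), L[:, i].copy()
    raise ModelSpecError(f"unknown matrix {kind!r}")


def expected_information(
    spec: ModelSpecification,
    data: Sequence[GroupMoments],
    table: ParamTable,
    mats: Sequence[ModelMatrices],
    extra: Optional[list[tuple[int, str, int, int]]] = None,
) -> np.ndarray:
    """Expected (Fisher) information of F at the given matrices.

    H_jk = sum_g w_g [ tr(iSigma dSigma_j iSigma dSigma_k)
                       + 2 dmu_j' iSigma dmu_k ]

    ``extra`` appends candidate cells (for score tests) after the free
    parameters.
    """
    n_total = sum(g.n for g in data)
    use_means = spec.mean_structure
    entries: list[list[tuple[int, str, int, int]]] = [fp.addresses for fp in table.free]
    if extra:
        entries.extend([[addr] for addr in extra])
    q = len(entries)
    H = np.zeros((q, q))
    for gi, (g, mat) in enumerate(zip(data, mats)):
        sigma, mu = implied_moments(mat)
        isig = np.linalg.inv(sigma)
        w = g.n / n_total
        ys, dmus, idxs = [], [], []
        for k, addrs in enumerate(entries):
            dS = None
            dmu = None
            for (gj, kind, i, j) in addrs:
                if gj != gi:
                    continue
                d1, d2 = delta_matrices(mat, (kind, i, j), use_means)
                dS = d1 if dS is None else dS + d1
                if d2 is not None:
                    dmu = d2 if dmu is None else dmu + d2
            if dS is None and dmu is None:
                continue
            if dS is None:
                dS = np.zeros_like(sigma)
            ys.append((isig @ dS, dmu))
            idxs.append(k)
        for a, (Ya, da) in enumerate(ys):
            for b in range(a, len(ys)):
                Yb, db = ys[b]
                val = float(np.sum(Ya * Yb.T))
                if da is not None and db is not None:
                    val += 2.0 * float(da @ isig @ db)
                H[idxs[a], idxs[b]] += w * val
                if a != b:
                    H[idxs[b], idxs[a]] += w * val
    return H


# ---------------------------------------------------------------------------
# fit


@dataclass
class FitResult:
    """Converged estimates and fit statistics for one model/data pair."""

    spec: ModelSpecification
    data: list[GroupMoments]
    estimates: dict[str, tuple[float, float]]  # name -> (value, se)
    discrepancy: float
    chi_square: float
    df: int
    p_value: float
    per_group_discrepancy: list[float]
    converged: bool
    iterations: int
    n_total: int
    multiplier: float
    warnings_: list[str] = field(default_factory=list)
    # internals for diagnostics
    param_table: ParamTable = None
    matrices: list[ModelMatrices] = None
    information: np.ndarray = None
    x: np.ndarray = None

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "discrepancy": self.discrepancy,
            "per_group_discrepancy": list(self.per_group_discrepancy),
            "converged": self.converged,
            "iterations": self.iterations,
            "n_total": self.n_total,
            "warnings": list(self.warnings_),
            "estimates": {
                k: {"value": v, "se": se} for k, (v, se) in self.estimates.items()
            },
        }


def fit(
    spec: ModelSpecification,
    data: Sequence[GroupMoments],
    chi2_multiplier: str = "total",
    gtol: float = 1e-7,
    max_iter: int = 1000,
    compute_se: bool = True,
    extra_free: Optional[Sequence[tuple[str, str, str, str]]] = None,
) -> FitResult:
    """Fit a multi-group model by maximum likelihood.

    ``chi2_multiplier``: ``"total"`` gives T = (N - G) F (default);
    ``"group"`` gives T = sum_g (N_g - 1) F_g.

    ``extra_free`` frees additional structurally-zero cells, each given
    as (group, matrix, row, col) with row/col as variable or latent
    names — the refitting counterpart of a modification index.
    """
    spec = spec.validate()
    if len(data) != len(spec.groups):
        raise EstimationError(
            f"model declares {len(spec.groups)} group(s) but {len(data)} supplied"
        )
    data = [align_to_model(g, spec) for g in data]
    df = degrees_of_freedom(spec)  # raises when under-identified

    table = build_param_table(spec, data)
    if extra_free:
        observed = {v: i for i, v in enumerate(spec.observed_variables)}
        latent = {v: i for i, v in enumerate(spec.latent_names)}
        gidx = {g: i for i, g in enumerate(spec.groups)}
        for group, mat_name, row, col in extra_free:
            addr = ParamAddress(mat_name, row, col, group)
            mat, i, j = _address_indices(addr, observed, latent)
            table.free.append(
                _FreeParam(f"extra:{mat}[{row},{col}]@{group}", 0.0, [(gidx[group], mat, i, j)])
            )
        df -= len(extra_free)
        if df < 0:
            raise ModelSpecError("negative degrees of freedom after freeing extra cells")
    obj = _Objective(spec, data, table)
    x0 = np.array([fp.start for fp in table.free])

    n_eval = 0

    def fun(x):
        nonlocal n_eval
        n_eval += 1
        F, g, _ = obj.value_grad(x)
        return F, g

    converged = True
    if table.q > 0:
        res = optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        x = res.x
        # Fisher-scoring polish: expected-information Newton steps
        F, g, _ = obj.value_grad(x)
        for _ in range(50):
            if np.max(np.abs(g)) < gtol * 1e-2 or F >= _BIG:
                break
            mats = build_matrices(spec, data, table, x)
            H = expected_information(spec, data, table, mats)
            try:
                step = -np.linalg.solve(H + 1e-12 * np.eye(table.q), g)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            for _ in range(30):
                F_new, g_new, _ = obj.value_grad(x + t * step)
                if F_new <= F + 1e-14:
                    x = x + t * step
                    F, g = F_new, g_new
                    break
                t *= 0.5
            else:
                break
        converged = bool(np.max(np.abs(g)) < gtol) if table.q else True
        iterations = int(res.nit)
    else:
        x = x0
        iterations = 0

    F, g, per_group = obj.value_grad(x)
    if per_group is None:
        raise EstimationError("implied covariance not positive definite at the solution")
    mats = build_matrices(spec, data, table, x)

    n_total = obj.n_total
    G = len(spec.groups)
    if chi2_multiplier == "total":
        T = (n_total - G) * F
        n_mult = n_total - G
    elif chi2_multiplier == "group":
        T = sum((g_.n - 1) * fg for g_, fg in zip(data, per_group))
        n_mult = n_total - G
    else:
        raise EstimationError(f"unknown chi2_multiplier {chi2_multiplier!r}")
    T = max(T, 0.0)
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else 1.0

    warns: list[str] = []
    if not converged:
        warns.append("optimizer did not reach the gradient tolerance")
        logger.warning("fit did not converge (|g|_max=%.3g)", float(np.max(np.abs(g))))
    H = None
    ses = np.full(table.q, np.nan)
    if table.q:
        H = expected_information(spec, data, table, mats)
        if compute_se:
            try:
                cov_x = (2.0 / n_mult) * np.linalg.inv(H)
                d = np.diag(cov_x)
                ses = np.sqrt(np.maximum(d, 0.0))
                if np.any(d <= 0):
                    warns.append("non-positive information diagonal; some SEs undefined")
            except np.linalg.LinAlgError:
                warns.append("singular information matrix; standard errors unavailable")

    # Heywood screen
    for fp, val in zip(table.free, x):
        for gi, kind, i, j in fp.addresses:
            if kind in ("theta", "psi") and i == j and val < 0:
                warns.append(
                    f"Heywood case: negative variance estimate {fp.name} = {val:.4g}"
                )
                break

    estimates = {fp.name: (float(v), float(se)) for fp, v, se in zip(table.free, x, ses)}
    return FitResult(
        spec=spec, data=list(data), estimates=estimates,
        discrepancy=float(F), chi_square=float(T), df=df, p_value=p_value,
        per_group_discrepancy=[float(v) for v in per_group],
        converged=converged, iterations=iterations, n_total=n_total,
        multiplier=float(n_mult), warnings_=warns,
        param_table=table, matrices=mats, information=H, x=np.asarray(x, dtype=float),
    )


def to_all_eta(spec: ModelSpecification) -> ModelSpecification:
    """Re-express auxiliary exogenous latents on the endogenous side.

    The coefficient matrices are already held in all-eta form, so the
    conversion changes bookkeeping only: the converted specification
    exposes the candidate direct cause-to-indicator loadings to the
    diagnostics module.  Fit is identical by construction; the operation
    is idempotent and the identity when no auxiliary latents exist.
    """
    if not spec.auxiliary_latents or spec.all_eta:
        return spec if not spec.auxiliary_latents else replace(spec, all_eta=True)
    return replace(spec, all_eta=True)
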