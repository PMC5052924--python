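"""Synthetic multi-group data with injectable misspecifications.

Generates population moments and multivariate-normal samples from a
numerically specified true structure, so every stage of the assessment
pipeline is testable without external survey data.  The canned
two-group design mimics the 1989 Work Orientations survey scale: twelve
5-point work items (treated as continuous, matching how such covariance
matrices are analyzed) plus Sex and Age, with group sizes 648 and 823
and the published per-country marginal means and standard deviations.

Injections deform the population away from the fitted structure —
an extra common factor, a direct cause-to-indicator effect, an omitted
cross-loading, or a correlated error — so that detectability claims can
be exercised against known truths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import GroupMoments, write_covariance
from .estimator import EstimationError, ModelMatrices, implied_moments
from .invariance import add_auxiliary_causes
from .model_spec import ModelSpecification, parse_model

__all__ = ["MisspecInjection", "SimulationDesign", "population_moments",
           "draw_samples", "make_issp_like", "issp_configural_spec",
           "rescale_to_marker", "write_design_files", "TABLE1"]

# Published per-country marginal statistics for the twelve work items,
# Sex (1=male, 2=female) and Age (years): (mean, sd) pairs.
TABLE1 = {
    "GB": {
        "y1": (2.46, 1.073), "y2": (3.38, 0.956), "y3": (3.29, 1.030),
        "y4": (3.16, 1.218), "y5": (2.11, 0.852), "y6": (2.08, 0.838),
        "y7": (2.28, 0.951), "y8": (2.19, 0.937), "y9": (3.46, 1.253),
        "y10": (4.09, 1.115), "y11": (4.06, 1.100), "y12": (4.16, 1.067),
        "Sex": (1.44, 0.496), "Age": (39.31, 11.463),
    },
    "USA": {
        "y1": (2.09, 0.977), "y2": (3.22, 1.009), "y3": (3.00, 1.115),
        "y4": (2.82, 1.192), "y5": (2.12, 0.967), "y6": (2.09, 0.965),
        "y7": (2.07, 0.913), "y8": (2.24, 0.953), "y9": (3.48, 1.186),
        "y10": (3.97, 1.164), "y11": (4.14, 1.042), "y12": (4.10, 1.022),
        "Sex": (1.47, 0.499), "Age": (38.62, 11.914),
    },
}

_ISSP_N = (648, 823)

_CONFIGURAL_SYNTAX = """
groups: GB USA
Context =~ y1 y2 y3 y4
Content =~ y5 y6 y7 y8
Environment =~ y9 y10 y11 y12
"""


@dataclass(frozen=True)
class MisspecInjection:
    """A population-level deviation from the fitted structure.

    kind / target:
      - ``direct_aux_effect`` and ``omitted_cross_loading``:
        (indicator, latent); ``magnitude`` is the standardized effect.
      - ``error_covariance``: (indicator_a, indicator_b); ``magnitude``
        is the error correlation.
      - ``extra_common_factor``: tuple of indicators; ``magnitude`` is
        the standardized loading of each on the extra factor.
    """

    kind: str
    target: tuple[str, ...]
    magnitude: float
    groups: Optional[tuple[str, ...]] = None  # default: all groups


@dataclass
class SimulationDesign:
    """A true model with numeric parameter values, sizes and a seed."""

    spec: ModelSpecification
    matrices: list[ModelMatrices]
    n_per_group: tuple[int, ...]
    seed: int = 0
    injections: tuple[MisspecInjection, ...] = ()

    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.spec.groups)


def _apply_injection(
    mat: ModelMatrices, inj: MisspecInjection
) -> ModelMatrices:
    sigma0, _ = implied_moments(mat)
    obs = {v: i for i, v in enumerate(mat.observed)}
    lat = {v: i for i, v in enumerate(mat.latent)}
    m = len(mat.latent)
    A = np.linalg.inv(np.eye(m) - mat.beta)
    latent_var = np.diag(A @ mat.psi @ A.T)
    out = mat.copy()
    if inj.kind in ("direct_aux_effect", "omitted_cross_loading"):
        ind, latent = inj.target
        i, j = obs[ind], lat[latent]
        raw = inj.magnitude * np.sqrt(sigma0[i, i]) / np.sqrt(latent_var[j])
        out.lam[i, j] += raw
    elif inj.kind == "error_covariance":
        a, b = obs[inj.target[0]], obs[inj.target[1]]
        raw = inj.magnitude * np.sqrt(mat.theta[a, a] * mat.theta[b, b])
        out.theta[a, b] += raw
        out.theta[b, a] += raw
    elif inj.kind == "extra_common_factor":
        p = len(mat.observed)
        out.lam = np.hstack([out.lam, np.zeros((p, 1))])
        out.beta = np.pad(out.beta, ((0, 1), (0, 1)))
        out.psi = np.pad(out.psi, ((0, 1), (0, 1)))
        out.psi[m, m] = 1.0
        out.latent = tuple(mat.latent) + ("_extra",)
        if out.alpha is not None:
            out.alpha = np.append(out.alpha, 0.0)
        for ind in inj.target:
            i = obs[ind]
            out.lam[i, m] = inj.magnitude * np.sqrt(sigma0[i, i])
    else:
        raise ValueError(f"unknown injection kind {inj.kind!r}")
    return out


def population_moments(
    design: SimulationDesign,
) -> list[tuple[np.ndarray, Optional[np.ndarray]]]:
    """Exact implied moments of the true structure, injections applied."""
    out = []
    for g, mat in zip(design.spec.groups, design.matrices):
        for inj in design.injections:
            if inj.groups is None or g in inj.groups:
                mat = _apply_injection(mat, inj)
        sigma, mu = implied_moments(mat)
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                f"group {g!r}: population covariance not positive definite "
                "after injections"
            ) from exc
        out.append((sigma, mu))
    return out


def draw_samples(
    design: SimulationDesign, return_raw: bool = False
):
    """Multivariate-normal samples per group; seeded and reproducible.

    One master seed spawns per-group child streams through
    ``numpy.random.SeedSequence``, so group g's draw is invariant to
    the other groups' sizes.
    """
    pops = population_moments(design)
    children = np.random.SeedSequence(design.seed).spawn(len(pops))
    moments: list[GroupMoments] = []
    raws: list[pd.DataFrame] = []
    names = tuple(design.spec.observed_variables)
    for (sigma, mu), child, n, label in zip(
        pops, children, design.n_per_group, design.spec.groups
    ):
        if n < len(names) + 1:
            raise ValueError(f"group {label!r}: n={n} is below p+1")
        rng = np.random.default_rng(child)
        mean = mu if mu is not None else np.zeros(len(names))
        x = rng.multivariate_normal(mean, sigma, size=n, method="cholesky")
        df = pd.DataFrame(x, columns=list(names))
        moments.append(
            GroupMoments(
                label=label, n=n, cov=df.cov(ddof=1).to_numpy(),
                variable_names=names, means=df.mean().to_numpy(),
            )
        )
        if return_raw:
            raws.append(df)
    return (moments, raws) if return_raw else moments


def issp_configural_spec(mean_structure: bool = False) -> ModelSpecification:
    """The three-factor, twelve-indicator, two-group configural model."""
    spec = parse_model(_CONFIGURAL_SYNTAX)
    return replace(spec, mean_structure=mean_structure).validate()


def make_issp_like(
    n_per_group: tuple[int, int] = _ISSP_N,
    seed: int = 0,
    injections: Sequence[MisspecInjection] = (),
    std_loading: float = 0.7,
    factor_corr: float = 0.3,
    aux_effect: float = 0.15,
    aux_corr: float = 0.05,
    aux_error_proportion: float = 0.02,
    group_invariant: bool = False,
) -> SimulationDesign:
    """A ready-made two-group design emulating the Work Orientations scale.

    Truth: three work factors (four indicators each, standardized
    loadings ``std_loading``, inter-factor correlations
    ``factor_corr``), influenced by correlated single-indicator causes
    Sex and Age (standardized effects ``aux_effect``, correlation
    ``aux_corr``, measurement error ``aux_error_proportion`` of the
    indicator variance).  Marginal means and standard deviations match
    the published per-country table; group sizes default to 648 (GB)
    and 823 (USA).  The published source gives no inter-factor or
    structural values, so those defaults are arbitrary fixture choices.

    ``group_invariant=True`` gives both groups the first group's
    marginals, making every measurement parameter exactly equal across
    groups — the null condition for ladder calibration studies.
    """
    spec = add_auxiliary_causes(
        issp_configural_spec(), ["Sex", "Age"], aux_error_proportion
    )
    factors = ["Context", "Content", "Environment"]
    lat_names = spec.latent_names  # factors then Sex, Age
    obs_names = spec.observed_variables
    m, p = len(lat_names), len(obs_names)
    li = {v: i for i, v in enumerate(lat_names)}
    oi = {v: i for i, v in enumerate(obs_names)}

    mats: list[ModelMatrices] = []
    for g in spec.groups:
        stats_g = TABLE1[spec.groups[0]] if group_invariant else TABLE1[g]
        D = np.array([stats_g[v][1] for v in obs_names])
        means = np.array([stats_g[v][0] for v in obs_names])

        lam = np.zeros((p, m))
        beta = np.zeros((m, m))
        psi = np.zeros((m, m))
        theta = np.zeros((p, p))
        # standardized structure first (unit observed variances)
        for latent in spec.common_factors:
            for a in latent.indicators:
                i = oi[a.indicator_name]
                lam[i, li[latent.name]] = std_loading
                theta[i, i] = 1.0 - std_loading**2
        for aux in ("Sex", "Age"):
            j = li[aux]
            lam[oi[aux], j] = 1.0
            theta[oi[aux], oi[aux]] = aux_error_proportion
            psi[j, j] = 1.0 - aux_error_proportion
        s, a_ = li["Sex"], li["Age"]
        psi[s, a_] = psi[a_, s] = aux_corr * np.sqrt(psi[s, s] * psi[a_, a_])
        gamma = np.zeros((len(factors), 2))
        gamma[:, 0] = aux_effect / np.sqrt(psi[s, s])   # standardized effects
        gamma[:, 1] = aux_effect / np.sqrt(psi[a_, a_])
        phi_aux = psi[np.ix_([s, a_], [s, a_])]
        explained = gamma @ phi_aux @ gamma.T  # factor (co)variance due to Sex/Age
        for fi, f in enumerate(factors):
            beta[li[f], s] = gamma[fi, 0]
            beta[li[f], a_] = gamma[fi, 1]
        for fi, f in enumerate(factors):
            psi[li[f], li[f]] = 1.0 - explained[fi, fi]
            for fj in range(fi + 1, len(factors)):
                cov = factor_corr - explained[fi, fj]
                psi[li[f], li[factors[fj]]] = psi[li[factors[fj]], li[f]] = cov
        # rescale to the published marginal metric
        lam = D[:, None] * lam
        theta = np.outer(D, D) * theta
        tau = means  # latent means zero, so intercepts carry the marginals
        alpha = np.zeros(m)
        mats.append(
            ModelMatrices(tuple(obs_names), tuple(lat_names),
                          lam, beta, psi, theta, tau, alpha)
        )
    return SimulationDesign(
        spec=spec, matrices=mats, n_per_group=tuple(n_per_group),
        seed=seed, injections=tuple(injections),
    )


def rescale_to_marker(
    mat: ModelMatrices, spec: ModelSpecification
) -> ModelMatrices:
    """Re-express true matrices in the marker-identified parameterization.

    Each latent is rescaled so its scaling indicator's loading is
    exactly 1.0; implied moments are unchanged.  Lets tests compare
    fitted estimates against a truth constructed on another scale.
    """
    out = mat.copy()
    scale = np.ones(len(mat.latent))
    oi = {v: i for i, v in enumerate(mat.observed)}
    for j, name in enumerate(mat.latent):
        latent = spec.latent(name)
        marker = next(a for a in latent.indicators if a.is_scaling)
        scale[j] = mat.lam[oi[marker.indicator_name], j]
    C = np.diag(scale)
    Cinv = np.diag(1.0 / scale)
    out.lam = mat.lam @ Cinv
    out.beta = C @ mat.beta @ Cinv
    out.psi = C @ mat.psi @ C
    if out.alpha is not None:
        out.alpha = C @ mat.alpha
    return out


def write_design_files(design: SimulationDesign, outdir: str) -> dict[str, dict[str, str]]:
    """Draw samples and write per-group covariance and raw-data files.

    Emits ``<label>.cov`` (full matrix with header) and ``<label>.csv``
    in exactly the dialects the input readers accept; returns the path
    map.
    """
    os.makedirs(outdir, exist_ok=True)
    moments, raws = draw_samples(design, return_raw=True)
    paths: dict[str, dict[str, str]] = {}
    for g, df in zip(moments, raws):
        cov_path = os.path.join(outdir, f"{g.label}.cov")
        csv_path = os.path.join(outdir, f"{g.label}.csv")
        write_covariance(g, cov_path)
        df.to_csv(csv_path, index=False, float_format="%.10g")
        paths[g.label] = {"cov": cov_path, "raw": csv_path, "n": str(g.n)}
    return paths
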