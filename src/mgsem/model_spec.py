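"""Multi-group model specifications.

A specification declares latent variables, their indicators, directed
paths among latents, and between-group equality constraints.  Everything
structural — free-parameter counts and degrees of freedom — is computed
here without touching data.

The internal parameterization is the all-eta (LISREL-style) form:

    y   = tau + Lambda @ eta + eps
    eta = alpha + B @ eta + zeta

with Lambda (p x m) loadings, B (m x m) latent paths, Psi (m x m)
latent/disturbance covariances, Theta (p x p) measurement error
covariances, and optional intercepts tau / latent means alpha.

Scaling follows the marker convention by default: the first indicator of
each common factor carries a fixed 1.0 loading.  Single-indicator
exogenous latents (auxiliary causes such as Sex or Age) carry a fixed
1.0 loading and a measurement error variance fixed to a stated
proportion of the indicator's sample variance.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "IndicatorAssignment",
    "LatentSpec",
    "PathSpec",
    "ParamAddress",
    "ConstraintSet",
    "ModelSpecification",
    "Parameter",
    "ModelSpecError",
    "parse_model",
    "serialize_model",
    "enumerate_parameters",
    "count_free_parameters",
    "degrees_of_freedom",
]

COMMON_FACTOR = "common_factor"
SINGLE_INDICATOR = "single_indicator_exogenous"

# parameter status markers
FREE = "free"
FIXED = "fixed"
FIXED_PROPORTIONAL = "fixed_proportional"  # value = proportion of sample variance


class ModelSpecError(ValueError):
    """Raised for invalid or inconsistent model specifications."""


@dataclass(frozen=True)
class IndicatorAssignment:
    indicator_name: str
    latent_name: str
    is_scaling: bool = False


@dataclass(frozen=True)
class LatentSpec:
    name: str
    kind: str = COMMON_FACTOR
    indicators: tuple[IndicatorAssignment, ...] = ()
    fixed_error_proportion: Optional[float] = None  # single-indicator kind only


@dataclass(frozen=True)
class PathSpec:
    cause: str
    effect: str


@dataclass(frozen=True)
class ParamAddress:
    """A single model-matrix cell in a single group.

    ``matrix`` is one of lambda/beta/psi/theta/tau/alpha; ``row`` and
    ``col`` are variable or latent *names* so addresses survive
    reordering.  For tau/alpha the column is the empty string.
    """

    matrix: str
    row: str
    col: str
    group: str


@dataclass
class ConstraintSet:
    """Equality constraints: each inner set is estimated as one value."""

    equality_groups: list[frozenset[ParamAddress]] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[ParamAddress] = set()
        for grp in self.equality_groups:
            if len(grp) < 2:
                raise ModelSpecError("equality group needs at least two addresses")
            mats = {a.matrix for a in grp}
            if len(mats) != 1:
                raise ModelSpecError(
                    f"equality group mixes parameter roles: {sorted(mats)}"
                )
            for a in grp:
                if a in seen:
                    raise ModelSpecError(f"address {a} appears in two equality groups")
                seen.add(a)


@dataclass
class ModelSpecification:
    groups: tuple[str, ...]
    latents: tuple[LatentSpec, ...]
    paths: tuple[PathSpec, ...] = ()
    exogenous_covariances: tuple[tuple[str, str], ...] = ()
    disturbance_covariances: tuple[tuple[str, str], ...] = ()
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    group_equal: tuple[str, ...] = ()  # loadings / residuals / intercepts
    mean_structure: bool = False
    scaling: str = "marker"  # or "factor_variance"
    all_eta: bool = False  # aux latents re-expressed on the endogenous side

    # ------------------------------------------------------------------ views
    @property
    def latent_names(self) -> list[str]:
        return [latent.name for latent in self.latents]

    @property
    def observed_variables(self) -> list[str]:
        """Canonical observed-variable order: indicators in declaration order."""
        out: list[str] = []
        for latent in self.latents:
            out.extend(a.indicator_name for a in latent.indicators)
        return out

    @property
    def common_factors(self) -> list[LatentSpec]:
        return [l for l in self.latents if l.kind == COMMON_FACTOR]

    @property
    def auxiliary_latents(self) -> list[LatentSpec]:
        return [l for l in self.latents if l.kind == SINGLE_INDICATOR]

    def latent(self, name: str) -> LatentSpec:
        for l in self.latents:
            if l.name == name:
                return l
        raise ModelSpecError(f"unknown latent {name!r}")

    def endogenous_latents(self) -> list[str]:
        effects = {p.effect for p in self.paths}
        return [l.name for l in self.latents if l.name in effects]

    def exogenous_latents(self) -> list[str]:
        effects = {p.effect for p in self.paths}
        return [l.name for l in self.latents if l.name not in effects]

    def indicator_owner(self, indicator: str) -> LatentSpec:
        for l in self.latents:
            if any(a.indicator_name == indicator for a in l.indicators):
                return l
        raise ModelSpecError(f"indicator {indicator!r} not assigned to any latent")

    def psi_pairs(self) -> list[tuple[str, str]]:
        """Free off-diagonal Psi cells.

        Latents on the same side freely covary by default: all pairs of
        exogenous latents (factor covariances, auxiliary-cause
        correlations) and all pairs of endogenous disturbances.
        Explicitly declared pairs are added on top.
        """
        exog = self.exogenous_latents()
        endo = self.endogenous_latents()
        pairs: list[tuple[str, str]] = []
        seen: set[frozenset[str]] = set()

        def add(a: str, b: str) -> None:
            key = frozenset((a, b))
            if a != b and key not in seen:
                seen.add(key)
                pairs.append((a, b))

        for a, b in itertools.combinations(exog, 2):
            add(a, b)
        for a, b in itertools.combinations(endo, 2):
            add(a, b)
        for a, b in self.exogenous_covariances + self.disturbance_covariances:
            add(a, b)
        return pairs

    # -------------------------------------------------------------- validation
    def validate(self) -> "ModelSpecification":
        if not self.groups:
            raise ModelSpecError("at least one group is required")
        if len(set(self.groups)) != len(self.groups):
            raise ModelSpecError("duplicate group labels")
        if not self.latents:
            raise ModelSpecError("at least one latent variable is required")
        if len(set(self.latent_names)) != len(self.latents):
            raise ModelSpecError("duplicate latent names")
        if self.scaling not in ("marker", "factor_variance"):
            raise ModelSpecError(f"unknown scaling convention {self.scaling!r}")

        seen_ind: set[str] = set()
        for latent in self.latents:
            if latent.kind not in (COMMON_FACTOR, SINGLE_INDICATOR):
                raise ModelSpecError(f"unknown latent kind {latent.kind!r}")
            if latent.kind == COMMON_FACTOR and not latent.indicators:
                raise ModelSpecError(f"common factor {latent.name!r} has no indicators")
            if latent.kind == SINGLE_INDICATOR:
                if len(latent.indicators) != 1:
                    raise ModelSpecError(
                        f"single-indicator latent {latent.name!r} needs exactly one indicator"
                    )
                prop = latent.fixed_error_proportion
                if prop is None or not (0.0 <= prop < 1.0):
                    raise ModelSpecError(
                        f"single-indicator latent {latent.name!r} needs a fixed error "
                        "proportion in [0, 1)"
                    )
            if latent.kind == COMMON_FACTOR and self.scaling == "marker":
                n_scaling = sum(a.is_scaling for a in latent.indicators)
                if n_scaling != 1:
                    raise ModelSpecError(
                        f"factor {latent.name!r} needs exactly one scaling indicator "
                        f"(found {n_scaling})"
                    )
            for a in latent.indicators:
                if a.latent_name != latent.name:
                    raise ModelSpecError(
                        f"indicator {a.indicator_name!r} assigned to {a.latent_name!r} "
                        f"but listed under {latent.name!r}"
                    )
                if a.indicator_name in seen_ind:
                    raise ModelSpecError(
                        f"indicator {a.indicator_name!r} assigned to more than one latent"
                    )
                seen_ind.add(a.indicator_name)

        names = set(self.latent_names)
        for p in self.paths:
            if p.cause == p.effect:
                raise ModelSpecError(f"self-loop on latent {p.cause!r}")
            for end in (p.cause, p.effect):
                if end not in names:
                    raise ModelSpecError(f"path references unknown latent {end!r}")
        self._check_acyclic()

        for a, b in self.exogenous_covariances + self.disturbance_covariances:
            for end in (a, b):
                if end not in names:
                    raise ModelSpecError(f"covariance references unknown latent {end!r}")
        for tag in self.group_equal:
            if tag not in ("loadings", "residuals", "intercepts"):
                raise ModelSpecError(f"unknown group_equal class {tag!r}")
        if "intercepts" in self.group_equal and not self.mean_structure:
            raise ModelSpecError("intercept constraints require a mean structure")
        self.constraints.validate()
        self._check_constraint_addresses()
        return self

    def _check_acyclic(self) -> None:
        adj: dict[str, list[str]] = {}
        for p in self.paths:
            adj.setdefault(p.cause, []).append(p.effect)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in adj.get(node, []):
                s = state.get(nxt, 0)
                if s == 1:
                    raise ModelSpecError(f"cycle in latent paths through {nxt!r}")
                if s == 0:
                    visit(nxt)
            state[node] = 2

        for node in list(adj):
            if state.get(node, 0) == 0:
                visit(node)

    def _check_constraint_addresses(self) -> None:
        cells = {
            (p.address.matrix, p.address.row, p.address.col, p.address.group): p.status
            for p in enumerate_parameters(self, expand_equalities=False)
        }
        for grp in self.constraints.equality_groups:
            for a in grp:
                status = cells.get((a.matrix, a.row, a.col, a.group))
                if status is None:
                    raise ModelSpecError(f"constraint targets unknown cell {a}")
                if status != FREE:
                    raise ModelSpecError(f"constraint targets a fixed cell {a}")


@dataclass
class Parameter:
    """One model-matrix cell with its estimation status.

    ``label`` groups equality-constrained cells: cells sharing a label
    are estimated as a single free parameter.
    """

    address: ParamAddress
    status: str  # FREE / FIXED / FIXED_PROPORTIONAL
    value: Optional[float] = None  # fixed value, or proportion for proportional
    label: Optional[str] = None


# ---------------------------------------------------------------------------
# parameter enumeration


def _expand_group_equal(spec: ModelSpecification, groups: tuple[str, ...]) -> list[frozenset[ParamAddress]]:
    if len(groups) < 2:
        return []
    out: list[frozenset[ParamAddress]] = []
    if "loadings" in spec.group_equal:
        for latent in spec.common_factors:
            for a in latent.indicators:
                if a.is_scaling and spec.scaling == "marker":
                    continue
                out.append(
                    frozenset(
                        ParamAddress("lambda", a.indicator_name, latent.name, g)
                        for g in groups
                    )
                )
    if "residuals" in spec.group_equal:
        for latent in spec.common_factors:
            for a in latent.indicators:
                out.append(
                    frozenset(
                        ParamAddress("theta", a.indicator_name, a.indicator_name, g)
                        for g in groups
                    )
                )
    if "intercepts" in spec.group_equal:
        for var in spec.observed_variables:
            out.append(
                frozenset(ParamAddress("tau", var, "", g) for g in groups)
            )
    return out


def enumerate_parameters(
    spec: ModelSpecification,
    group_count: Optional[int] = None,
    expand_equalities: bool = True,
) -> list[Parameter]:
    """Enumerate every model-matrix cell that the model governs.

    Returns one :class:`Parameter` per cell per group, with equality
    constraints applied as shared labels.  Off-diagonal Psi/Theta cells
    that are structurally zero are omitted (they are candidates for the
    diagnostics module, not parameters).
    """
    if group_count is None or group_count == len(spec.groups):
        groups = spec.groups
    else:
        groups = tuple(f"g{i + 1}" for i in range(group_count))

    params: list[Parameter] = []
    for g in groups:
        # loadings
        for latent in spec.latents:
            for a in latent.indicators:
                addr = ParamAddress("lambda", a.indicator_name, latent.name, g)
                if latent.kind == SINGLE_INDICATOR:
                    params.append(Parameter(addr, FIXED, 1.0))
                elif spec.scaling == "marker" and a.is_scaling:
                    params.append(Parameter(addr, FIXED, 1.0))
                else:
                    params.append(Parameter(addr, FREE))
        # measurement error variances
        for latent in spec.latents:
            for a in latent.indicators:
                addr = ParamAddress("theta", a.indicator_name, a.indicator_name, g)
                if latent.kind == SINGLE_INDICATOR:
                    params.append(
                        Parameter(addr, FIXED_PROPORTIONAL, latent.fixed_error_proportion)
                    )
                else:
                    params.append(Parameter(addr, FREE))
        # latent paths
        for p in spec.paths:
            params.append(Parameter(ParamAddress("beta", p.effect, p.cause, g), FREE))
        # latent (co)variances
        for latent in spec.latents:
            addr = ParamAddress("psi", latent.name, latent.name, g)
            if spec.scaling == "factor_variance" and latent.kind == COMMON_FACTOR:
                params.append(Parameter(addr, FIXED, 1.0))
            else:
                params.append(Parameter(addr, FREE))
        for a, b in spec.psi_pairs():
            params.append(Parameter(ParamAddress("psi", a, b, g), FREE))
        # mean structure
        if spec.mean_structure:
            for var in spec.observed_variables:
                params.append(Parameter(ParamAddress("tau", var, "", g), FREE))
            free_means = (
                "intercepts" in spec.group_equal and g != groups[0] and len(groups) > 1
            )
            for latent in spec.latents:
                addr = ParamAddress("alpha", latent.name, "", g)
                if free_means:
                    params.append(Parameter(addr, FREE))
                else:
                    params.append(Parameter(addr, FIXED, 0.0))

    if expand_equalities:
        sets = list(spec.constraints.equality_groups)
        sets.extend(_expand_group_equal(spec, groups))
        by_addr = {p.address: p for p in params}
        for k, grp in enumerate(sets):
            a0 = min(grp, key=lambda a: (a.matrix, a.row, a.col, a.group))
            label = f"eq{k}:{a0.matrix}[{a0.row},{a0.col or '-'}]"
            for a in grp:
                p = by_addr.get(a)
                if p is None:
                    raise ModelSpecError(f"constraint targets unknown cell {a}")
                if p.status != FREE:
                    raise ModelSpecError(f"constraint targets a fixed cell {a}")
                if p.label is not None and p.label != label:
                    raise ModelSpecError(f"address {a} appears in two equality groups")
                p.label = label
    return params


def count_free_parameters(
    spec: ModelSpecification, group_count: Optional[int] = None
) -> int:
    """Distinct free parameters after fixing and equality constraints."""
    params = enumerate_parameters(spec, group_count)
    labels: set[str] = set()
    n_unlabeled = 0
    for p in params:
        if p.status != FREE:
            continue
        if p.label is None:
            n_unlabeled += 1
        else:
            labels.add(p.label)
    return n_unlabeled + len(labels)


def degrees_of_freedom(
    spec: ModelSpecification,
    observed_per_group: Optional[int] = None,
    group_count: Optional[int] = None,
) -> int:
    """Model degrees of freedom: total sample moments minus free parameters.

    Each group contributes p(p+1)/2 covariance moments, plus p means
    when the mean structure is on.
    """
    p = len(spec.observed_variables)
    if observed_per_group is not None and observed_per_group != p:
        raise ModelSpecError(
            f"observed_per_group={observed_per_group} but the model names {p} indicators"
        )
    G = group_count if group_count is not None else len(spec.groups)
    moments = G * (p * (p + 1) // 2)
    if spec.mean_structure:
        moments += G * p
    df = moments - count_free_parameters(spec, group_count)
    if df < 0:
        raise ModelSpecError(f"negative degrees of freedom ({df}): under-identified model")
    return df


# ---------------------------------------------------------------------------
# model syntax

_OP_RE = re.compile(r"^(?P<lhs>\S+)\s*(?P<op>=~|~~|~)\s*(?P<rhs>.+)$")


def parse_model(text: str) -> ModelSpecification:
    """Parse the line-oriented model syntax.

    Lines (``#`` starts a comment)::

        groups: GB USA
        means: on
        Context =~ y1 y2 y3 y4        # first indicator scales the factor
        single: Sex error=0.02        # single-indicator exogenous latent
        Context ~ Sex Age             # latent paths (cause on the right)
        Sex ~~ Age                    # explicit latent covariance
        group_equal: loadings         # between-group equality class
        equal: lambda y2 Context GB USA   # a custom equality constraint
    """
    groups: tuple[str, ...] = ("g1",)
    latents: list[LatentSpec] = []
    paths: list[PathSpec] = []
    exo_cov: list[tuple[str, str]] = []
    dist_cov: list[tuple[str, str]] = []
    group_equal: list[str] = []
    custom: list[frozenset[ParamAddress]] = []
    mean_structure = False
    scaling = "marker"

    def err(line_no: int, msg: str) -> ModelSpecError:
        return ModelSpecError(f"line {line_no}: {msg}")

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("groups:"):
            groups = tuple(line.split(":", 1)[1].split())
            if not groups:
                raise err(line_no, "groups: needs at least one label")
            continue
        if line.startswith("means:"):
            val = line.split(":", 1)[1].strip().lower()
            if val not in ("on", "off"):
                raise err(line_no, f"means: expects on/off, got {val!r}")
            mean_structure = val == "on"
            continue
        if line.startswith("scaling:"):
            scaling = line.split(":", 1)[1].strip()
            continue
        if line.startswith("group_equal:"):
            group_equal.extend(line.split(":", 1)[1].split())
            continue
        if line.startswith("single:"):
            body = line.split(":", 1)[1].split()
            if not body:
                raise err(line_no, "single: needs a variable name")
            name = body[0]
            prop = 0.02
            for tok in body[1:]:
                if tok.startswith("error="):
                    prop = float(tok.split("=", 1)[1])
                else:
                    raise err(line_no, f"unknown single: option {tok!r}")
            latents.append(
                LatentSpec(
                    name,
                    SINGLE_INDICATOR,
                    (IndicatorAssignment(name, name, is_scaling=True),),
                    fixed_error_proportion=prop,
                )
            )
            continue
        if line.startswith("equal:"):
            body = line.split(":", 1)[1].split()
            if len(body) < 5:
                raise err(line_no, "equal: needs <matrix> <row> <col> <group> <group> ...")
            mat, row, col = body[0], body[1], body[2]
            col = "" if col == "-" else col
            custom.append(
                frozenset(ParamAddress(mat, row, col, g) for g in body[3:])
            )
            continue
        m = _OP_RE.match(line)
        if not m:
            raise err(line_no, f"cannot parse {line!r}")
        lhs, op, rhs_toks = m.group("lhs"), m.group("op"), m.group("rhs").split()
        if op == "=~":
            inds = tuple(
                IndicatorAssignment(name, lhs, is_scaling=(i == 0))
                for i, name in enumerate(rhs_toks)
            )
            if not inds:
                raise err(line_no, f"factor {lhs!r} lists no indicators")
            latents.append(LatentSpec(lhs, COMMON_FACTOR, inds))
        elif op == "~":
            for cause in rhs_toks:
                paths.append(PathSpec(cause=cause, effect=lhs))
        else:  # ~~
            if len(rhs_toks) != 1:
                raise err(line_no, "a ~~ line covaries exactly two latents")
            exo_cov.append((lhs, rhs_toks[0]))

    spec = ModelSpecification(
        groups=groups,
        latents=tuple(latents),
        paths=tuple(paths),
        exogenous_covariances=tuple(exo_cov),
        disturbance_covariances=tuple(dist_cov),
        constraints=ConstraintSet(custom),
        group_equal=tuple(dict.fromkeys(group_equal)),
        mean_structure=mean_structure,
        scaling=scaling,
    )
    return spec.validate()


def serialize_model(spec: ModelSpecification) -> str:
    """Emit model syntax that :func:`parse_model` reads back losslessly."""
    lines = [f"groups: {' '.join(spec.groups)}"]
    if spec.mean_structure:
        lines.append("means: on")
    if spec.scaling != "marker":
        lines.append(f"scaling: {spec.scaling}")
    for latent in spec.latents:
        if latent.kind == SINGLE_INDICATOR:
            lines.append(f"single: {latent.name} error={latent.fixed_error_proportion}")
        else:
            inds = " ".join(a.indicator_name for a in latent.indicators)
            lines.append(f"{latent.name} =~ {inds}")
    by_effect: dict[str, list[str]] = {}
    for p in spec.paths:
        by_effect.setdefault(p.effect, []).append(p.cause)
    for effect, causes in by_effect.items():
        lines.append(f"{effect} ~ {' '.join(causes)}")
    for a, b in spec.exogenous_covariances + spec.disturbance_covariances:
        lines.append(f"{a} ~~ {b}")
    if spec.group_equal:
        lines.append(f"group_equal: {' '.join(spec.group_equal)}")
    for grp in spec.constraints.equality_groups:
        addrs = sorted(grp, key=lambda a: a.group)
        a0 = addrs[0]
        col = a0.col if a0.col else "-"
        gs = " ".join(a.group for a in addrs)
        lines.append(f"equal: {a0.matrix} {a0.row} {col} {gs}")
    return "\n".join(lines) + "\n"


def with_constraints(
    spec: ModelSpecification, *classes: str
) -> ModelSpecification:
    """Copy of ``spec`` with additional between-group equality classes."""
    tags = tuple(dict.fromkeys(spec.group_equal + classes))
    return replace(spec, group_equal=tags)
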