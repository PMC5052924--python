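"""Sample-moment input: covariance files, raw data tables, alignment.

Covariance files are plain text: a header row of variable names followed
by a numeric body, either the full symmetric matrix or the lower
triangle (row ``i`` holding ``i+1`` entries).  Raw data are rectangular
CSV tables with a declared missing-value code; moments are computed
with listwise deletion and divisor n-1.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_spec import ModelSpecification

__all__ = ["GroupMoments", "read_covariance", "write_covariance",
           "moments_from_raw", "align_to_model", "DataError"]

logger = logging.getLogger(__name__)

_SYM_RTOL = 1e-8


class DataError(ValueError):
    """Raised for invalid moment or raw-data input."""


@dataclass
class GroupMoments:
    """One group's sample size, covariance matrix, and optional means."""

    label: str
    n: int
    cov: np.ndarray
    variable_names: tuple[str, ...]
    means: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        self.variable_names = tuple(self.variable_names)
        p = len(self.variable_names)
        if self.n < 2:
            raise DataError(f"group {self.label!r}: sample size must be >= 2")
        if self.cov.shape != (p, p):
            raise DataError(
                f"group {self.label!r}: covariance is {self.cov.shape} but "
                f"{p} variables are named"
            )
        scale = max(1.0, float(np.max(np.abs(self.cov))))
        if np.max(np.abs(self.cov - self.cov.T)) > _SYM_RTOL * scale:
            raise DataError(f"group {self.label!r}: covariance matrix is not symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if np.any(np.diag(self.cov) <= 0):
            raise DataError(f"group {self.label!r}: non-positive variance on the diagonal")
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            if self.means.shape != (p,):
                raise DataError(f"group {self.label!r}: means length mismatch")

    @property
    def p(self) -> int:
        return len(self.variable_names)


def _tokenize(source: Union[str, os.PathLike]) -> list[list[str]]:
    if isinstance(source, (str,)) and "\n" not in str(source) and os.path.exists(source):
        text = open(source, "r", encoding="utf-8").read()
    elif isinstance(source, os.PathLike):
        text = open(source, "r", encoding="utf-8").read()
    else:
        text = str(source)
    rows = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rows.append(line.replace(",", " ").split())
    return rows


def read_covariance(
    source: Union[str, os.PathLike],
    n: int,
    format: str = "full",
    label: str = "g1",
    means: Optional[Sequence[float]] = None,
) -> GroupMoments:
    """Read a covariance matrix (path or literal text) into GroupMoments.

    ``format`` is ``"full"`` or ``"lower_triangular"``; the lower
    triangle is symmetrized exactly.
    """
    rows = _tokenize(source)
    if not rows:
        raise DataError("empty covariance input")
    names = tuple(rows[0])
    p = len(names)
    body = rows[1:]
    if len(body) != p:
        raise DataError(f"expected {p} matrix rows after the header, found {len(body)}")
    cov = np.zeros((p, p))
    if format == "full":
        for i, row in enumerate(body):
            if len(row) != p:
                raise DataError(f"row {i + 1}: expected {p} entries, found {len(row)}")
            cov[i] = [float(x) for x in row]
    elif format in ("lower_triangular", "lower"):
        for i, row in enumerate(body):
            if len(row) != i + 1:
                raise DataError(
                    f"row {i + 1}: expected {i + 1} lower-triangular entries, "
                    f"found {len(row)}"
                )
            vals = [float(x) for x in row]
            cov[i, : i + 1] = vals
            cov[: i + 1, i] = vals
    else:
        raise DataError(f"unknown covariance format {format!r}")
    return GroupMoments(label=label, n=n, cov=cov, variable_names=names, means=means)


def write_covariance(moments: GroupMoments, path: Union[str, os.PathLike]) -> None:
    """Write the full covariance matrix with a variable-name header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(moments.variable_names) + "\n")
        for row in moments.cov:
            fh.write(" ".join(format(x, ".10g") for x in row) + "\n")


def moments_from_raw(
    table: Union[pd.DataFrame, str, os.PathLike],
    missing_code: Optional[float] = None,
    deletion: str = "listwise",
    label: str = "g1",
) -> GroupMoments:
    """Compute sample moments from a rectangular raw-data table.

    Rows containing the missing code are dropped (listwise deletion);
    the covariance uses divisor n-1 and means are complete-case means.
    """
    if deletion != "listwise":
        raise DataError(f"unsupported deletion scheme {deletion!r}")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    df = table.apply(pd.to_numeric, errors="coerce")
    if missing_code is not None:
        df = df.mask(df == missing_code)
    df = df.dropna()
    n = len(df)
    if n < 2:
        raise DataError(f"fewer than 2 complete cases after listwise deletion (n={n})")
    return GroupMoments(
        label=label,
        n=n,
        cov=df.cov(ddof=1).to_numpy(),
        variable_names=tuple(df.columns),
        means=df.mean().to_numpy(),
    )


def align_to_model(
    moments: GroupMoments, spec: ModelSpecification
) -> GroupMoments:
    """Permute moments to the model's canonical variable order.

    Variables the model does not name are dropped with a logged
    warning; a model variable absent from the data is an error.
    """
    want = spec.observed_variables
    have = {name: i for i, name in enumerate(moments.variable_names)}
    missing = [v for v in want if v not in have]
    if missing:
        raise DataError(
            f"group {moments.label!r}: model variable(s) {missing} absent from data"
        )
    extra = [v for v in moments.variable_names if v not in set(want)]
    if extra:
        logger.warning(
            "group %r: dropping %d variable(s) not in the model: %s",
            moments.label, len(extra), extra,
        )
    idx = [have[v] for v in want]
    return GroupMoments(
        label=moments.label,
        n=moments.n,
        cov=moments.cov[np.ix_(idx, idx)],
        variable_names=tuple(want),
        means=None if moments.means is None else moments.means[idx],
    )
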