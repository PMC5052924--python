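"""Independent SEM oracle for cross-checking the estimator.

Implements the implied covariance by the RAM (reticular action model)
formulation — one asymmetric matrix over observed + latent variables
and a filter — which shares no code or algebra path with the package's
all-eta implementation, and minimizes the ML discrepancy by
finite-difference quasi-Newton with its own parameter bookkeeping.
Deliberately slow and naive; used only on tiny models.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


class OracleGroup:
    """One group's RAM matrices: nv = p observed + m latent variables."""

    def __init__(self, p: int, m: int):
        self.p, self.m = p, m
        nv = p + m
        self.A = np.zeros((nv, nv))  # directed: A[to, from]
        self.S = np.zeros((nv, nv))  # symmetric (co)variances

    def implied(self) -> np.ndarray:
        nv = self.p + self.m
        ia = np.linalg.inv(np.eye(nv) - self.A)
        full = ia @ self.S @ ia.T
        return full[: self.p, : self.p]


class OracleModel:
    """Free parameters: list of (share_key, [(group, 'A'|'S', i, j), ...])."""

    def __init__(self, groups: list[OracleGroup], params, starts):
        self.groups = groups
        self.params = params
        self.starts = np.asarray(starts, dtype=float)

    def _assign(self, x):
        for val, (_, cells) in zip(x, self.params):
            for g, mat, i, j in cells:
                M = self.groups[g].A if mat == "A" else self.groups[g].S
                M[i, j] = val
                if mat == "S":
                    M[j, i] = val

    def discrepancy(self, x, data) -> float:
        self._assign(x)
        n_total = sum(n for _, n in data)
        F = 0.0
        for g, (S_obs, n) in zip(self.groups, data):
            sigma = g.implied()
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e8
            sign_s, logdet_s = np.linalg.slogdet(S_obs)
            isig = np.linalg.inv(sigma)
            F += (n / n_total) * (
                logdet + np.trace(S_obs @ isig) - logdet_s - g.p
            )
        return F

    def fit(self, data):
        res = optimize.minimize(
            self.discrepancy, self.starts, args=(data,), method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10},
        )
        res = optimize.minimize(
            self.discrepancy, res.x, args=(data,), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-14},
        )
        n_total = sum(n for _, n in data)
        T = (n_total - len(self.groups)) * max(res.fun, 0.0)
        return res.x, res.fun, T


def random_factor_model(rng: np.random.Generator):
    """A random small factor structure: truth matrices plus bookkeeping.

    1-2 factors, 2-3 indicators each (<=6 observed), 1-2 groups.
    Returns (n_factors, inds_per_factor, n_groups, truth) where truth
    holds per-group loadings, factor covariances and error variances.
    """
    n_factors = int(rng.integers(1, 3))
    inds = int(rng.integers(2, 4)) if n_factors == 2 else int(rng.integers(3, 4))
    n_groups = int(rng.integers(1, 3))
    truth = []
    for _ in range(n_groups):
        lam = []
        for _f in range(n_factors):
            lam.append([1.0] + list(rng.uniform(0.5, 1.3, inds - 1)))
        phi = np.eye(n_factors) * rng.uniform(0.6, 1.4, n_factors)
        if n_factors == 2:
            r = rng.uniform(-0.4, 0.6)
            cov = r * np.sqrt(phi[0, 0] * phi[1, 1])
            phi[0, 1] = phi[1, 0] = cov
        theta = rng.uniform(0.3, 0.9, n_factors * inds)
        truth.append({"lam": lam, "phi": phi, "theta": theta})
    return n_factors, inds, n_groups, truth
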