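"""Estimator: implied moments, discrepancy, fitting, all-eta conversion."""

import dataclasses

import numpy as np
import pytest

from mgsem import (
    GroupMoments,
    ModelMatrices,
    fit,
    implied_moments,
    ml_discrepancy,
    parse_model,
    to_all_eta,
)
from mgsem.estimator import EstimationError, _Objective, build_param_table
from mgsem.model_spec import ModelSpecError, with_constraints
from mgsem.synthetic import rescale_to_marker


def _mats(lam, beta, psi, theta):
    lam = np.atleast_2d(np.asarray(lam, float))
    p, m = lam.shape
    return ModelMatrices(
        tuple(f"y{i}" for i in range(p)), tuple(f"e{j}" for j in range(m)),
        lam, np.asarray(beta, float), np.asarray(psi, float), np.asarray(theta, float),
    )


class TestImpliedMoments:
    def test_identity_mapping(self):
        psi = np.array([[1.0, 0.3], [0.3, 2.0]])
        sigma, mu = implied_moments(_mats(np.eye(2), np.zeros((2, 2)), psi, np.zeros((2, 2))))
        assert np.allclose(sigma, psi)
        assert mu is None

    def test_single_factor_hand_algebra(self):
        # loadings 1 and 2, factor variance 1, error variances 1
        sigma, _ = implied_moments(
            _mats([[1.0], [2.0]], np.zeros((1, 1)), [[1.0]], np.eye(2))
        )
        assert np.allclose(sigma, [[2.0, 2.0], [2.0, 5.0]])

    def test_cyclic_unit_product_is_singular(self):
        beta = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(EstimationError, match="singular"):
            implied_moments(_mats(np.eye(2), beta, np.eye(2), np.zeros((2, 2))))


class TestDiscrepancy:
    def test_zero_at_perfect_fit(self):
        S = np.array([[2.0, 0.5], [0.5, 1.5]])
        g = GroupMoments("g1", 100, S, ("y0", "y1"))
        assert ml_discrepancy([g], [(S, None)]) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        # p=1, S=2, Sigma=1: ln 1 + 2 - ln 2 - 1
        g = GroupMoments("g1", 50, np.array([[2.0]]), ("y0",))
        F = ml_discrepancy([g], [(np.array([[1.0]]), None)])
        assert F == pytest.approx(1.0 - np.log(2.0), abs=1e-12)

    def test_group_order_symmetry(self):
        S1 = np.array([[2.0, 0.3], [0.3, 1.0]])
        S2 = np.array([[1.5, 0.1], [0.1, 2.5]])
        sig = np.eye(2) * 1.7
        a = GroupMoments("a", 120, S1, ("y0", "y1"))
        b = GroupMoments("b", 80, S2, ("y0", "y1"))
        assert ml_discrepancy([a, b], [(sig, None), (sig, None)]) == pytest.approx(
            ml_discrepancy([b, a], [(sig, None), (sig, None)]), abs=1e-12
        )


class TestFit:
    def test_analytic_gradient_matches_numeric(self, two_factor_spec, two_factor_data):
        table = build_param_table(two_factor_spec, two_factor_data)
        obj = _Objective(two_factor_spec, two_factor_data, table)
        x0 = np.array([fp.start for fp in table.free]) * 1.05 + 0.01
        _, g, _ = obj.value_grad(x0)
        eps = 1e-6
        for k in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += eps
            xm[k] -= eps
            num = (obj.value_grad(xp)[0] - obj.value_grad(xm)[0]) / (2 * eps)
            assert g[k] == pytest.approx(num, abs=1e-6)

    def test_population_moment_recovery(self, issp_design, issp_population_data):
        res = fit(issp_design.spec, issp_population_data)
        assert res.converged
        assert res.chi_square < 1e-8
        truth = [rescale_to_marker(m, issp_design.spec) for m in issp_design.matrices]
        for fp, val in zip(res.param_table.free, res.x):
            gi, kind, i, j = fp.addresses[0]
            tm = truth[gi]
            want = {"lambda": tm.lam, "beta": tm.beta,
                    "psi": tm.psi, "theta": tm.theta}[kind][i, j]
            assert val == pytest.approx(want, abs=1e-7)

    def test_simulation_recovery_within_monte_carlo_error(self):
        spec = parse_model("groups: g1 g2\nF1 =~ a b c\nF2 =~ d e f\n")
        rng = np.random.default_rng(9)
        lam = np.zeros((6, 2))
        lam[:3, 0] = [1.0, 0.8, 1.2]
        lam[3:, 1] = [1.0, 0.9, 0.7]
        phi = np.array([[1.0, 0.35], [0.35, 0.8]])
        theta_d = [0.5, 0.6, 0.4, 0.5, 0.7, 0.6]
        sigma = lam @ phi @ lam.T + np.diag(theta_d)
        data = []
        for glabel in ("g1", "g2"):
            x = rng.multivariate_normal(np.zeros(6), sigma, size=1000)
            data.append(GroupMoments(glabel, 1000, np.cov(x, rowvar=False, ddof=1),
                                     tuple("abcdef")))
        res = fit(spec, data)
        assert res.converged
        truth = {"lambda": lam, "psi": phi, "theta": np.diag(theta_d)}
        for name, (val, se) in res.estimates.items():
            fp = next(f for f in res.param_table.free if f.name == name)
            _, kind, i, j = fp.addresses[0]
            assert abs(val - truth[kind][i, j]) < 3 * se + 1e-9

    def test_underidentified_spec_is_a_precondition_error(self):
        spec = parse_model("groups: g1\nF =~ y1 y2\n")
        g = GroupMoments("g1", 100, np.eye(2) + 0.4, ("y1", "y2"))
        with pytest.raises(ModelSpecError, match="under-identified"):
            fit(spec, [g])

    def test_scale_equivariance(self, two_factor_spec, two_factor_data):
        base = fit(two_factor_spec, two_factor_data)
        c = 10.0
        g = two_factor_data[0]
        D = np.ones(6)
        D[1] = c  # rescale indicator b (a free-loading indicator)
        scaled = GroupMoments("g1", g.n, g.cov * np.outer(D, D), g.variable_names)
        res = fit(two_factor_spec, [scaled])
        assert res.chi_square == pytest.approx(base.chi_square, abs=1e-6)
        assert res.estimates["lambda[b,F1]@g1"][0] == pytest.approx(
            c * base.estimates["lambda[b,F1]@g1"][0], rel=1e-6
        )
        assert res.estimates["theta[b,b]@g1"][0] == pytest.approx(
            c**2 * base.estimates["theta[b,b]@g1"][0], rel=1e-6
        )

    def test_constraints_never_decrease_chi_square(self, fig1_spec, issp_sample):
        base = fit(fig1_spec, issp_sample)
        metric = fit(with_constraints(fig1_spec, "loadings"), issp_sample)
        strict = fit(with_constraints(fig1_spec, "loadings", "residuals"), issp_sample)
        assert metric.chi_square >= base.chi_square - 1e-8
        assert strict.chi_square >= metric.chi_square - 1e-8

    def test_group_multiplier_option(self, fig1_spec, issp_sample):
        total = fit(fig1_spec, issp_sample)
        group = fit(fig1_spec, issp_sample, chi2_multiplier="group")
        # same minimizer, slightly different scaling convention
        assert group.chi_square == pytest.approx(total.chi_square, rel=0.01)
        assert group.chi_square != total.chi_square


class TestAllEta:
    def test_identity_without_auxiliary_latents(self, fig1_spec):
        assert to_all_eta(fig1_spec) is fig1_spec

    def test_idempotent(self, aug_spec):
        once = to_all_eta(aug_spec)
        assert to_all_eta(once) == once

    def test_fit_unchanged_by_conversion(self, aug_spec, issp_sample):
        a = fit(aug_spec, issp_sample)
        b = fit(to_all_eta(aug_spec), issp_sample)
        assert b.chi_square == pytest.approx(a.chi_square, abs=1e-6)
        for name, (val, _) in a.estimates.items():
            assert b.estimates[name][0] == pytest.approx(val, abs=1e-6)
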