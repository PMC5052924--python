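"""Misfit localization: severity, modification indices, residuals, screens."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mgsem import (
    GroupMoments,
    descriptive_fit_indices,
    diagnose,
    fit,
    modification_indices,
    normalized_residuals,
    parse_model,
    screen,
    severity,
    to_all_eta,
)


class TestSeverity:
    def test_equal_statistic_and_df_gives_zero(self):
        z, p = severity(102.0, 102)
        assert z == pytest.approx(0.0)
        assert 0.4 < p < 0.6

    def test_zero_statistic(self):
        z, p = severity(0.0, 10)
        assert z < 0
        assert p == pytest.approx(1.0)

    def test_df_zero_is_flagged(self):
        with pytest.raises(ValueError, match="df = 0"):
            severity(5.0, 0)

    @given(st.floats(1.0, 500.0), st.floats(2.0, 600.0), st.integers(1, 200))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_statistic_and_exact_tail(self, t1, t2, df):
        z1, p1 = severity(t1, df)
        z2, p2 = severity(t2, df)
        if t2 > t1:
            assert z2 > z1 and p2 <= p1
        # exact chi-square upper tail, not the normal approximation
        assert p1 == pytest.approx(1.0 - stats.chi2.cdf(t1, df), abs=1e-12)


class TestModificationIndices:
    def test_free_cells_are_not_candidates(self, two_factor_fit):
        mis = modification_indices(two_factor_fit, "all")
        # no candidate duplicates a governed cell: governed loadings are
        # (indicator, owner) pairs, candidates are cross-loadings only
        owners = {a.indicator_name: l.name
                  for l in two_factor_fit.spec.latents for a in l.indicators}
        for r in mis:
            if r.matrix == "lambda":
                assert owners[r.row] != r.col
        assert all(r.mi >= 0 for r in mis)

    def test_omitted_cross_loading_has_maximum_mi(self):
        # population moments with a real cross-loading d<-F1 omitted by the model
        spec = parse_model("groups: g1\nF1 =~ a b c\nF2 =~ d e f\n")
        lam = np.zeros((6, 2))
        lam[:3, 0] = [1.0, 0.8, 1.2]
        lam[3:, 1] = [1.0, 0.9, 0.7]
        lam[3, 0] = 0.5  # the omitted path
        phi = np.array([[1.0, 0.35], [0.35, 0.8]])
        sigma = lam @ phi @ lam.T + np.diag([0.5, 0.6, 0.4, 0.5, 0.7, 0.6])
        g = GroupMoments("g1", 500, sigma, tuple("abcdef"))
        res = fit(spec, [g])
        top = modification_indices(res, "cross_loadings")[0]
        assert (top.matrix, top.row, top.col) == ("lambda", "d", "F1")


class TestResiduals:
    def test_perfect_fit_gives_zero_residuals(self, issp_design, issp_population_data):
        res = fit(issp_design.spec, issp_population_data)
        for mat in normalized_residuals(res).values():
            assert np.max(np.abs(mat)) < 1e-5

    def test_symmetric_for_sampled_fits(self, two_factor_fit):
        for mat in normalized_residuals(two_factor_fit).values():
            assert np.allclose(mat, mat.T)

    def test_normalization_calibrated_at_true_parameters(self):
        # evaluated at the true parameter values the entries are ~N(0,1),
        # so |r|>2 should occur for roughly 4.6% of moments; fitted
        # residuals are smaller still because free parameters absorb misfit
        import types

        from mgsem.estimator import ModelMatrices

        lam = np.zeros((6, 2))
        lam[:3, 0] = [1.0, 0.8, 1.2]
        lam[3:, 1] = [1.0, 0.9, 0.7]
        phi = np.array([[1.0, 0.35], [0.35, 0.8]])
        theta = np.diag([0.5, 0.6, 0.4, 0.5, 0.7, 0.6])
        sigma = lam @ phi @ lam.T + theta
        truth = ModelMatrices(
            tuple("abcdef"), ("F1", "F2"), lam, np.zeros((2, 2)), phi, theta
        )
        rng = np.random.default_rng(17)
        exceed, cells = 0, 0
        for _ in range(150):
            x = rng.multivariate_normal(np.zeros(6), sigma, size=500)
            g = GroupMoments("g1", 500, np.cov(x, rowvar=False, ddof=1), tuple("abcdef"))
            shim = types.SimpleNamespace(data=[g], matrices=[truth])
            mat = normalized_residuals(shim)["g1"]
            iu = np.triu_indices(6)
            exceed += int(np.sum(np.abs(mat[iu]) > 2.0))
            cells += len(iu[0])
        rate = exceed / cells
        assert 0.02 < rate < 0.08


class TestScreen:
    def test_aux_block_enumerates_24_candidates_per_group(self, aug_spec, issp_sample):
        res = fit(to_all_eta(aug_spec), issp_sample)
        report = diagnose(res, candidates="direct_aux_effects")
        blk = screen(report, "aux_direct")
        assert blk["candidates"] == 24 * len(aug_spec.groups)
        per_group = {
            g: sum(r.group == g for r in report.mod_indices) for g in aug_spec.groups
        }
        assert all(v == 24 for v in per_group.values())
        # the new-moment block: 2 aux x 12 indicators per group
        assert blk["resid_cells"] == 24 * len(aug_spec.groups)

    def test_unknown_block_is_an_error(self, two_factor_fit):
        report = diagnose(two_factor_fit)
        with pytest.raises(ValueError, match="unknown block"):
            screen(report, "nonsense")

    def test_counts_are_consistent_with_listed_values(self, two_factor_fit):
        report = diagnose(two_factor_fit)
        assert report.counts["mi_exceed"] == sum(
            r.mi > report.mi_threshold for r in report.mod_indices
        )


def test_descriptive_indices_labelled_and_sane(issp_design, issp_population_data):
    res = fit(issp_design.spec, issp_population_data)
    idx = descriptive_fit_indices(res)
    assert idx["rmsea"] == pytest.approx(0.0, abs=1e-6)
    assert idx["cfi"] == pytest.approx(1.0, abs=1e-6)
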