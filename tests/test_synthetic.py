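"""Synthetic designs: population moments, sampling, injections."""

import dataclasses

import numpy as np
import pytest

from mgsem import (
    MisspecInjection,
    draw_samples,
    fit,
    issp_configural_spec,
    make_issp_like,
    moments_from_raw,
    population_moments,
    read_covariance,
)
from mgsem.estimator import EstimationError, implied_moments
from mgsem.synthetic import TABLE1, write_design_files


class TestPopulationMoments:
    def test_consistent_with_implied_moments(self, issp_design):
        pops = population_moments(issp_design)
        for mat, (sigma, mu) in zip(issp_design.matrices, pops):
            s2, m2 = implied_moments(mat)
            assert np.allclose(sigma, s2)
            assert np.allclose(mu, m2)

    def test_zero_magnitude_injection_is_identity(self, issp_design):
        injected = dataclasses.replace(
            issp_design,
            injections=(MisspecInjection("direct_aux_effect", ("y1", "Sex"), 0.0),),
        )
        for (s1, _), (s2, _) in zip(
            population_moments(issp_design), population_moments(injected)
        ):
            assert np.allclose(s1, s2)

    def test_pd_breaking_injection_is_an_error(self, issp_design):
        bad = dataclasses.replace(
            issp_design,
            injections=(MisspecInjection("error_covariance", ("y1", "y2"), 3.0),),
        )
        with pytest.raises(EstimationError, match="positive definite"):
            population_moments(bad)

    def test_extra_factor_truth_is_detectable_in_population(self, fig1_spec):
        # a fourth common cause spanning the three clusters: the
        # three-factor configural model must misfit even exact moments
        design = make_issp_like(
            injections=(
                MisspecInjection(
                    "extra_common_factor", ("y1", "y2", "y5", "y6", "y9", "y10"), 0.4
                ),
            )
        )
        from mgsem import GroupMoments

        names = tuple(design.spec.observed_variables)
        data = [
            GroupMoments(label=g, n=n, cov=s, variable_names=names, means=m)
            for g, n, (s, m) in zip(
                design.spec.groups, design.n_per_group, population_moments(design)
            )
        ]
        res = fit(fig1_spec, data)
        assert res.chi_square > 50.0  # strictly detectable at survey-scale n


class TestDrawSamples:
    def test_seed_determinism(self, issp_design):
        a = draw_samples(issp_design)
        b = draw_samples(issp_design)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.cov, gb.cov)
            assert np.array_equal(ga.means, gb.means)

    def test_large_sample_approaches_population(self):
        design = make_issp_like(n_per_group=(100_000, 100_000), seed=5)
        pops = population_moments(design)
        for g, (sigma, mu) in zip(draw_samples(design), pops):
            d = np.sqrt(np.diag(sigma))
            corr_pop = sigma / np.outer(d, d)
            ds = np.sqrt(np.diag(g.cov))
            corr_smp = g.cov / np.outer(ds, ds)
            assert np.max(np.abs(corr_smp - corr_pop)) < 0.02

    def test_marginals_match_published_table_at_survey_n(self, issp_sample):
        for g in issp_sample:
            stats_g = TABLE1[g.label]
            for i, name in enumerate(g.variable_names):
                mean, sd = stats_g[name]
                se_sd = sd / np.sqrt(2 * g.n)
                assert abs(np.sqrt(g.cov[i, i]) - sd) < 5 * se_sd
                assert abs(g.means[i] - mean) < 5 * sd / np.sqrt(g.n)


class TestIsspDesign:
    def test_default_group_sizes(self, issp_design):
        assert issp_design.n_per_group == (648, 823)
        assert issp_design.spec.groups == ("GB", "USA")

    def test_configural_rejection_near_alpha_under_three_factor_truth(self):
        spec = issp_configural_spec()
        rej = 0
        R = 60
        for r in range(R):
            data = draw_samples(make_issp_like(seed=5000 + r))
            rej += fit(spec, data, compute_se=False).p_value < 0.05
        assert rej <= 10  # ~alpha * R, generously bounded

    def test_emitted_files_round_trip(self, tmp_path, issp_design):
        design = dataclasses.replace(issp_design, n_per_group=(200, 220))
        paths = write_design_files(design, str(tmp_path))
        sample = draw_samples(design)
        for g in sample:
            from_cov = read_covariance(paths[g.label]["cov"], n=g.n, label=g.label)
            assert np.allclose(from_cov.cov, g.cov, atol=1e-8)
            from_raw = moments_from_raw(paths[g.label]["raw"], label=g.label)
            assert from_raw.n == g.n
            assert np.allclose(from_raw.cov, g.cov, atol=1e-6)
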