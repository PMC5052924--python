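import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from mgsem import (
    GroupMoments,
    add_auxiliary_causes,
    draw_samples,
    fit,
    issp_configural_spec,
    make_issp_like,
    population_moments,
    parse_model,
)

TWO_FACTOR = """
groups: g1
F1 =~ a b c
F2 =~ d e f
"""


@pytest.fixture(scope="session")
def fig1_spec():
    """Two-group, three-factor, twelve-indicator configural model."""
    return issp_configural_spec()


@pytest.fixture(scope="session")
def aug_spec(fig1_spec):
    return add_auxiliary_causes(fig1_spec, ["Sex", "Age"], 0.02)


@pytest.fixture(scope="session")
def issp_design():
    return make_issp_like(seed=7)


@pytest.fixture(scope="session")
def issp_sample(issp_design):
    return draw_samples(issp_design)


@pytest.fixture(scope="session")
def issp_population_data(issp_design):
    names = tuple(issp_design.spec.observed_variables)
    return [
        GroupMoments(label=g, n=n, cov=sigma, variable_names=names, means=mu)
        for g, n, (sigma, mu) in zip(
            issp_design.spec.groups, issp_design.n_per_group,
            population_moments(issp_design),
        )
    ]


@pytest.fixture(scope="session")
def two_factor_spec():
    return parse_model(TWO_FACTOR)


@pytest.fixture(scope="session")
def two_factor_data(two_factor_spec):
    rng = np.random.default_rng(42)
    lam = np.zeros((6, 2))
    lam[:3, 0] = [1.0, 0.8, 1.2]
    lam[3:, 1] = [1.0, 0.9, 0.7]
    phi = np.array([[1.0, 0.35], [0.35, 0.8]])
    theta = np.diag([0.5, 0.6, 0.4, 0.5, 0.7, 0.6])
    sigma = lam @ phi @ lam.T + theta
    x = rng.multivariate_normal(np.zeros(6), sigma, size=500)
    return [
        GroupMoments(
            label="g1", n=500, cov=np.cov(x, rowvar=False, ddof=1),
            variable_names=tuple("abcdef"),
        )
    ]


@pytest.fixture(scope="session")
def two_factor_fit(two_factor_spec, two_factor_data):
    return fit(two_factor_spec, two_factor_data)
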