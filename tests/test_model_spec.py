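"""Structural tests: parsing, parameter counting, degrees of freedom."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from mgsem import (
    add_auxiliary_causes,
    count_free_parameters,
    degrees_of_freedom,
    parse_model,
    serialize_model,
)
from mgsem.model_spec import (
    ConstraintSet,
    ModelSpecError,
    ModelSpecification,
    ParamAddress,
    with_constraints,
)

SURVIVOR = """
groups: GB USA
Context =~ y2 y3
Content =~ y5 y6 y8
Environment =~ y9 y10 y12
single: Sex error=0.02
single: Age error=0.02
Context ~ Sex Age
Content ~ Sex Age
Environment ~ Sex Age
"""


class TestParsing:
    def test_configural_shape(self, fig1_spec):
        assert len(fig1_spec.observed_variables) == 12
        assert len(fig1_spec.common_factors) == 3
        assert fig1_spec.groups == ("GB", "USA")
        # exactly one scaling indicator per factor, the first listed
        for latent in fig1_spec.common_factors:
            scaling = [a for a in latent.indicators if a.is_scaling]
            assert len(scaling) == 1 and scaling[0] is latent.indicators[0]

    def test_round_trip_is_lossless(self, aug_spec):
        text = serialize_model(aug_spec)
        again = parse_model(text)
        assert serialize_model(again) == text
        assert again.observed_variables == aug_spec.observed_variables
        assert degrees_of_freedom(again) == degrees_of_freedom(aug_spec)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("groups: a b\n", "at least one latent"),
            ("F =~ y1 y2\nG =~ y2 y3\n", "more than one latent"),
            ("F =~ y1 y2\nF ~ Ghost\n", "unknown latent"),
            ("F =~ y1 y2\nG =~ y3 y4\nF ~ G\nG ~ F\n", "cycle"),
            ("single: Sex error=1.5\n", "error"),
        ],
    )
    def test_invalid_specifications_rejected(self, text, match):
        with pytest.raises(ModelSpecError, match=match):
            parse_model(text)


class TestCounting:
    def test_configural_free_parameters(self, fig1_spec):
        # per group: 9 loadings + 12 error variances + 3 factor variances
        # + 3 factor covariances
        assert count_free_parameters(fig1_spec, group_count=1) == 27
        assert count_free_parameters(fig1_spec) == 54

    def test_augmented_free_parameters(self, aug_spec):
        # adds 6 paths, 2 auxiliary variances, 1 auxiliary covariance,
        # 3 disturbance variances and 3 disturbance covariances, while the
        # 3 factor variances/covariances move to the disturbance side
        assert count_free_parameters(aug_spec, group_count=1) == 36

    def test_equality_constraint_reduces_count_by_group_links(self, fig1_spec):
        metric = with_constraints(fig1_spec, "loadings")
        assert count_free_parameters(fig1_spec) - count_free_parameters(metric) == 9


class TestDegreesOfFreedom:
    def test_configural_df(self, fig1_spec):
        assert degrees_of_freedom(fig1_spec) == 102
        assert degrees_of_freedom(fig1_spec, group_count=1) == 51

    def test_augmented_df(self, fig1_spec, aug_spec):
        assert degrees_of_freedom(aug_spec) == 138
        # 18 new df per group: 24 new moments explained by 6 new paths,
        # net of the auxiliary variance/covariance parameters
        assert (
            degrees_of_freedom(aug_spec, group_count=1)
            - degrees_of_freedom(fig1_spec, group_count=1)
            == 18
        )

    def test_survivor_model_df(self):
        assert degrees_of_freedom(parse_model(SURVIVOR)) == 54

    def test_saturated_model_df_zero(self):
        spec = parse_model("groups: g1\nF =~ y1 y2 y3\n")
        assert degrees_of_freedom(spec) == 0

    def test_underidentified_is_an_error(self):
        spec = parse_model("groups: g1\nF =~ y1 y2\n")
        with pytest.raises(ModelSpecError, match="under-identified"):
            degrees_of_freedom(spec)

    def test_observed_count_mismatch_is_an_error(self, fig1_spec):
        with pytest.raises(ModelSpecError):
            degrees_of_freedom(fig1_spec, observed_per_group=13)

    def test_invariant_under_group_relabel_and_reorder(self, fig1_spec):
        relabeled = dataclasses.replace(fig1_spec, groups=("USA", "GB"))
        assert degrees_of_freedom(relabeled) == degrees_of_freedom(fig1_spec)
        reordered = dataclasses.replace(
            fig1_spec, latents=tuple(reversed(fig1_spec.latents))
        )
        assert degrees_of_freedom(reordered) == degrees_of_freedom(fig1_spec)

    @given(st.sampled_from(["y2", "y3", "y4", "y6", "y7", "y10"]))
    @settings(deadline=None, max_examples=6)
    def test_one_equality_constraint_adds_one_df(self, indicator):
        spec = parse_model(
            "groups: GB USA\n"
            "Context =~ y1 y2 y3 y4\nContent =~ y5 y6 y7 y8\n"
            "Environment =~ y9 y10 y11 y12\n"
        )
        owner = spec.indicator_owner(indicator).name
        constrained = dataclasses.replace(
            spec,
            constraints=ConstraintSet(
                [frozenset(
                    ParamAddress("lambda", indicator, owner, g) for g in spec.groups
                )]
            ),
        )
        assert degrees_of_freedom(constrained) == degrees_of_freedom(spec) + 1


def test_add_auxiliary_causes_structure(fig1_spec, aug_spec):
    assert len(aug_spec.paths) == 6
    assert [l.name for l in aug_spec.auxiliary_latents] == ["Sex", "Age"]
    assert add_auxiliary_causes(fig1_spec, []) is fig1_spec
    with pytest.raises(ModelSpecError, match="already an indicator"):
        add_auxiliary_causes(fig1_spec, ["y1"])
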