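"""Closed-form risk decomposition and indirect subgroup RR estimation."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxindirect import (
    EffectEstimate,
    ExtrapolationWarning,
    InputInconsistencyError,
    Prevalence,
    Scenario,
    check_rare_event_assumption,
    decompose_marginal_risk,
    indirect_subgroup_rr,
    subgroup_risk_table,
)

ratios = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)
probabilities = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
interior_probs = st.floats(min_value=1e-3, max_value=0.5, allow_nan=False)


class TestDecomposeMarginalRisk:
    @pytest.mark.parametrize(
        "marginal, prevalence, rr_assoc, expected",
        [
            (0.10, 0.28, 1.18, (0.112338, 0.095202)),
            (0.10, 0.28, 1.0, (0.10, 0.10)),
            # zero prevalence: marker-negative risk is the marginal itself,
            # marker-positive is the RR-scaled extrapolation
            (0.10, 0.0, 5.0, (0.50, 0.10)),
        ],
    )
    def test_known_values(self, marginal, prevalence, rr_assoc, expected):
        pos, neg = decompose_marginal_risk(marginal, prevalence, rr_assoc)
        assert pos == pytest.approx(expected[0], abs=1e-6)
        assert neg == pytest.approx(expected[1], abs=1e-6)

    @pytest.mark.parametrize(
        "marginal, prevalence, rr_assoc, exc",
        [
            (0.0, 0.28, 1.18, ValueError),
            (1.0, 0.28, 1.18, ValueError),
            (0.10, 0.28, 0.0, ValueError),
            (0.10, 0.28, -2.0, ValueError),
            # marker-positive risk would be 50·0.9/... >= 1
            (0.9, 0.01, 50.0, InputInconsistencyError),
        ],
    )
    def test_invalid_inputs_rejected(self, marginal, prevalence, rr_assoc, exc):
        with pytest.raises(exc):
            decompose_marginal_risk(marginal, prevalence, rr_assoc)

    def test_inconsistency_error_names_inputs(self):
        with pytest.raises(InputInconsistencyError, match="rr_assoc=50"):
            decompose_marginal_risk(0.9, 0.01, 50.0)

    @given(marginal=interior_probs, prevalence=probabilities, rr_assoc=ratios)
    @settings(max_examples=300, derandomize=True)
    def test_conservation(self, marginal, prevalence, rr_assoc):
        """Prevalence-weighted re-aggregation recovers the marginal risk."""
        try:
            pos, neg = decompose_marginal_risk(marginal, prevalence, rr_assoc)
        except InputInconsistencyError:
            return
        assert prevalence * pos + (1 - prevalence) * neg == pytest.approx(
            marginal, abs=1e-12
        )


class TestIndirectSubgroupRR:
    @pytest.mark.parametrize(
        "rr_overall, rr_a, rr_b, prevalence, expected",
        [
            # CYP2C19 case study: printed full-precision / 2-dp values
            (0.84, 1.0, 1.18, 0.28, (0.747742, 0.882336)),
            # equal association in both arms: purely prognostic marker
            (0.84, 1.3, 1.3, 0.28, (0.84, 0.84)),
            (0.84, 1.0, 1.6, 0.28, (0.61320, 0.98112)),
        ],
    )
    def test_known_values(self, rr_overall, rr_a, rr_b, prevalence, expected):
        pos, neg = indirect_subgroup_rr(rr_overall, rr_a, rr_b, prevalence)
        assert pos == pytest.approx(expected[0], abs=5e-6)
        assert neg == pytest.approx(expected[1], abs=5e-6)

    def test_case_study_rounds_to_published_values(self):
        pos, neg = indirect_subgroup_rr(0.84, 1.0, 1.18, 0.28)
        assert (round(pos, 2), round(neg, 2)) == (0.75, 0.88)

    @pytest.mark.parametrize(
        "rr_overall, rr_a, rr_b, prevalence, expected",
        [
            (0.84, 1.0, 1.18, 0.28, None),
            (0.84, 1.0, 1.6, 0.28, None),
            (1.3, 2.0, 0.7, 0.6, None),
        ],
    )
    def test_agrees_with_brute_force_solver(
        self, brute_force_oracle, rr_overall, rr_a, rr_b, prevalence, expected
    ):
        """The closed form matches an independent numerical root-find."""
        pos, neg = indirect_subgroup_rr(rr_overall, rr_a, rr_b, prevalence)
        oracle_pos, oracle_neg = brute_force_oracle(rr_overall, rr_a, rr_b, prevalence)
        assert pos == pytest.approx(oracle_pos, abs=1e-9)
        assert neg == pytest.approx(oracle_neg, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_ratios_rejected(self, bad):
        with pytest.raises(ValueError):
            indirect_subgroup_rr(bad, 1.0, 1.18, 0.28)
        with pytest.raises(ValueError):
            indirect_subgroup_rr(0.84, 1.0, bad, 0.28)

    def test_empty_subgroup_flagged_as_extrapolated(self):
        with pytest.warns(ExtrapolationWarning, match="marker-positive"):
            pos, neg = indirect_subgroup_rr(0.84, 1.0, 1.18, 0.0)
        assert neg == pytest.approx(0.84)
        with pytest.warns(ExtrapolationWarning, match="marker-negative"):
            pos, neg = indirect_subgroup_rr(0.84, 1.0, 1.18, 1.0)
        assert pos == pytest.approx(0.84)

    @given(rr_overall=ratios, rr_a=ratios, rr_b=ratios,
           prevalence=st.floats(min_value=0.001, max_value=0.999))
    @settings(max_examples=300, derandomize=True)
    def test_interaction_identity(self, rr_overall, rr_a, rr_b, prevalence):
        """RR_pos / RR_neg equals the ratio of the association RRs."""
        pos, neg = indirect_subgroup_rr(rr_overall, rr_a, rr_b, prevalence)
        assert pos / neg == pytest.approx(rr_a / rr_b, rel=1e-12)

    @given(rr_overall=ratios, rr_assoc=ratios,
           prevalence=st.floats(min_value=0.001, max_value=0.999))
    @settings(max_examples=200, derandomize=True)
    def test_purely_prognostic_marker_inherits_overall_effect(
        self, rr_overall, rr_assoc, prevalence
    ):
        pos, neg = indirect_subgroup_rr(rr_overall, rr_assoc, rr_assoc, prevalence)
        assert pos == pytest.approx(rr_overall, rel=1e-12)
        assert neg == pytest.approx(rr_overall, rel=1e-12)

    @given(rr_overall=ratios, rr_a=ratios, rr_b=ratios)
    @settings(max_examples=200, derandomize=True)
    def test_degenerate_prevalence_returns_overall_rr(self, rr_overall, rr_a, rr_b):
        with pytest.warns(ExtrapolationWarning):
            _, neg = indirect_subgroup_rr(rr_overall, rr_a, rr_b, 0.0)
        assert neg == pytest.approx(rr_overall, rel=1e-12)
        with pytest.warns(ExtrapolationWarning):
            pos, _ = indirect_subgroup_rr(rr_overall, rr_a, rr_b, 1.0)
        assert pos == pytest.approx(rr_overall, rel=1e-12)


class TestSubgroupRiskTable:
    def test_case_study_without_marginal_risks(self, case_study):
        effect = subgroup_risk_table(case_study)
        assert effect.rr_marker_pos == pytest.approx(0.747742, abs=1e-6)
        assert effect.rr_marker_neg == pytest.approx(0.882336, abs=1e-6)
        assert effect.risk_by_arm_and_marker is None

    def test_cross_arm_risk_ratios_reproduce_subgroup_rrs(self, case_study):
        scenario = dataclasses.replace(
            case_study, marginal_risk_beta=0.10, marginal_risk_alpha=0.084
        )
        effect = subgroup_risk_table(scenario)
        risks = effect.risk_by_arm_and_marker
        assert set(risks) == {("alpha", "pos"), ("alpha", "neg"),
                              ("beta", "pos"), ("beta", "neg")}
        assert all(0 < r < 1 for r in risks.values())
        ratio_pos = risks[("alpha", "pos")] / risks[("beta", "pos")]
        ratio_neg = risks[("alpha", "neg")] / risks[("beta", "neg")]
        assert ratio_pos == pytest.approx(effect.rr_marker_pos, abs=1e-12)
        assert ratio_neg == pytest.approx(effect.rr_marker_neg, abs=1e-12)
        # each arm's prevalence-weighted average recovers its marginal risk
        p = scenario.prevalence.point
        assert p * risks[("alpha", "pos")] + (1 - p) * risks[("alpha", "neg")] == (
            pytest.approx(0.084, abs=1e-12)
        )
        assert p * risks[("beta", "pos")] + (1 - p) * risks[("beta", "neg")] == (
            pytest.approx(0.10, abs=1e-12)
        )

    def test_no_association_equal_marginals_gives_unit_rrs(self, case_study):
        scenario = dataclasses.replace(
            case_study,
            rr_assoc_alpha=EffectEstimate.fixed(1.3),
            rr_assoc_beta=EffectEstimate.fixed(1.3),
            rr_overall=EffectEstimate.fixed(1.0),
            marginal_risk_alpha=0.10,
            marginal_risk_beta=0.10,
        )
        effect = subgroup_risk_table(scenario)
        risks = effect.risk_by_arm_and_marker
        assert effect.rr_marker_pos == pytest.approx(1.0)
        assert effect.rr_marker_neg == pytest.approx(1.0)
        for marker in ("pos", "neg"):
            assert risks[("alpha", marker)] == pytest.approx(risks[("beta", marker)])


class TestRareEventAssumption:
    def make(self, case_study, alpha=None, beta=None):
        return dataclasses.replace(
            case_study, marginal_risk_alpha=alpha, marginal_risk_beta=beta
        )

    def test_boundary_not_exceeded_is_silent(self, case_study):
        assert check_rare_event_assumption(self.make(case_study, 0.084, 0.10)) == []

    def test_high_risk_warns(self, case_study):
        warnings = check_rare_event_assumption(self.make(case_study, beta=0.35))
        assert len(warnings) == 1
        assert "0.35" in warnings[0] and "clopidogrel" in warnings[0]

    def test_no_marginal_risks_is_silent(self, case_study):
        assert check_rare_event_assumption(case_study) == []


class TestTypeInvariants:
    def test_effect_estimate_ci_must_bracket_point(self):
        with pytest.raises(ValueError, match="bracket"):
            EffectEstimate(point=0.84, ci_low=0.90, ci_high=0.92)

    def test_effect_estimate_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            EffectEstimate(point=-0.5, ci_low=-0.6, ci_high=-0.4)

    def test_fixed_estimate_is_degenerate(self):
        e = EffectEstimate.fixed(1.0)
        assert e.is_fixed and e.point == e.ci_low == e.ci_high == 1.0

    @pytest.mark.parametrize("point", [-0.1, 1.2])
    def test_prevalence_range(self, point):
        with pytest.raises(ValueError):
            Prevalence(point=point)

    def test_prevalence_ci_must_bracket(self):
        with pytest.raises(ValueError):
            Prevalence(point=0.28, ci_low=0.30, ci_high=0.40)

    def test_scenario_rejects_bad_marginal_risk(self, case_study):
        with pytest.raises(ValueError, match="marginal_risk_beta"):
            Scenario(
                prevalence=case_study.prevalence,
                rr_assoc_alpha=case_study.rr_assoc_alpha,
                rr_assoc_beta=case_study.rr_assoc_beta,
                rr_overall=case_study.rr_overall,
                marginal_risk_beta=1.5,
            )
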