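"""Fuzzy engine: membership shapes, Mamdani inference, the 3×3 rule
base and the fuzzy XML dialect."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinescreen.fuzzy_engine import (
    FuzzyError,
    FuzzyRule,
    Gaussian,
    LinguisticVariable,
    LVarBinding,
    MembershipFunction,
    NoRuleFiredError,
    RuleBase3x3,
    SPINE_RULE_BASE,
    Trapezoid,
    Universe,
    aggregate_and_defuzzify,
    evaluate_fuzzy_policy,
    expand_rule_base,
    fuzzify,
    gaussian_membership,
    parse_fuzzy_policy,
    rule_firing_strength,
    serialize_fuzzy_policy,
    trapezoid_membership,
)
from spinescreen.pdl_model import PolicySchemaError

finite = st.floats(allow_nan=False, allow_infinity=False,
                   min_value=-1e6, max_value=1e6)


class TestGaussianMembership:
    def test_unity_at_center(self):
        assert gaussian_membership(3.0, center=3.0, sigma=0.5) == 1.0

    def test_one_sigma_from_center(self):
        # closed form: exp(−1/2)
        value = gaussian_membership(2.5, center=2.0, sigma=0.5)
        assert value == pytest.approx(math.exp(-0.5), rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(center=finite, d=finite,
           sigma=st.floats(min_value=1e-3, max_value=1e3))
    def test_symmetric_and_bounded(self, center, d, sigma):
        lo = gaussian_membership(center - d, center, sigma)
        hi = gaussian_membership(center + d, center, sigma)
        # center ± d round differently in float, hence approx not ==
        assert lo == pytest.approx(hi, rel=1e-9, abs=1e-12)
        assert 0.0 <= lo <= 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(FuzzyError, match="sigma"):
            gaussian_membership(0.0, 0.0, 0.0)


class TestTrapezoidMembership:
    def test_plateau_ramps_and_support(self):
        a, b, c, d = 1.0, 2.0, 4.0, 6.0
        assert trapezoid_membership(3.0, a, b, c, d) == 1.0
        assert trapezoid_membership(1.5, a, b, c, d) == pytest.approx(0.5)
        assert trapezoid_membership(5.0, a, b, c, d) == pytest.approx(0.5)
        assert trapezoid_membership(0.9, a, b, c, d) == 0.0
        assert trapezoid_membership(6.1, a, b, c, d) == 0.0

    def test_degenerate_edge_is_crisp_step(self):
        # a == b: membership jumps to 1 at the shared point
        assert trapezoid_membership(1.0, 1.0, 1.0, 2.0, 3.0) == 1.0
        assert trapezoid_membership(3.0, 0.0, 1.0, 3.0, 3.0) == 1.0

    def test_unordered_parameters_rejected(self):
        with pytest.raises(FuzzyError, match="a ≤ b ≤ c ≤ d"):
            trapezoid_membership(0.0, 2.0, 1.0, 3.0, 4.0)

    def test_bounded_on_random_inputs(self):
        # 10^5 random points per shape stay within [0, 1]
        rng = np.random.default_rng(11)
        x = rng.uniform(-50, 50, 100_000)
        trap = trapezoid_membership(x, -3.0, -1.0, 2.0, 10.0)
        gauss = gaussian_membership(x, 1.5, 4.0)
        for values in (trap, gauss):
            assert values.min() >= 0.0 and values.max() <= 1.0


def amplitude_lvar(policy):
    return policy.variable_map["LAmpl"]


class TestFuzzification:
    def test_healthy_amplitude_is_fully_medium(self, fuzzy_policy):
        grades = fuzzify(1.6, amplitude_lvar(fuzzy_policy))
        assert grades == {"Small": 0.0, "Medium": 1.0, "High": 0.0}

    def test_constrained_amplitude_is_fully_small(self, fuzzy_policy):
        grades = fuzzify(0.6, amplitude_lvar(fuzzy_policy))
        assert grades["Small"] == 1.0

    def test_out_of_universe_values_are_clamped(self, fuzzy_policy):
        lvar = amplitude_lvar(fuzzy_policy)
        assert fuzzify(-5.0, lvar) == fuzzify(0.0, lvar)
        assert fuzzify(99.0, lvar) == fuzzify(4.0, lvar)

    def test_grades_need_not_sum_to_one(self):
        lvar = LinguisticVariable(
            "V", "input", Universe(0, 1),
            (MembershipFunction("A", Trapezoid(0, 0, 1, 1)),
             MembershipFunction("B", Trapezoid(0, 0, 1, 1))))
        assert sum(fuzzify(0.5, lvar).values()) == 2.0


class TestRuleFiring:
    GRADES = {"LAmpl": {"Medium": 1.0}, "LWdth": {"Small": 0.583}}

    def test_min_conjunction(self):
        rule = FuzzyRule((("LAmpl", "Medium"), ("LWdth", "Small")),
                         ("LCond", "Small"))
        assert rule_firing_strength(rule, self.GRADES) == 0.583

    def test_zero_grade_annihilates(self):
        rule = FuzzyRule((("LAmpl", "Medium"), ("LWdth", "Small")),
                         ("LCond", "Small"))
        grades = {"LAmpl": {"Medium": 0.0}, "LWdth": {"Small": 0.9}}
        assert rule_firing_strength(rule, grades) == 0.0

    def test_single_antecedent_identity(self):
        rule = FuzzyRule((("LWdth", "Small"),), ("LCond", "Small"))
        assert rule_firing_strength(rule, self.GRADES) == 0.583

    def test_missing_grade_is_an_error(self):
        rule = FuzzyRule((("LAmpl", "High"),), ("LCond", "Small"))
        with pytest.raises(FuzzyError, match="missing grade"):
            rule_firing_strength(rule, self.GRADES)


def output_lvar(terms, lo=0.0, hi=1.0, resolution=1001):
    return LinguisticVariable(
        "LOut", "output", Universe(lo, hi, resolution),
        tuple(MembershipFunction(n, s) for n, s in terms))


class TestDefuzzification:
    def test_symmetric_consequent_centers_on_midpoint(self):
        lvar = output_lvar([("Mid", Trapezoid(0.3, 0.45, 0.55, 0.7))])
        rule = FuzzyRule((("X", "A"),), ("LOut", "Mid"))
        for strength in (0.2, 0.7, 1.0):
            out = aggregate_and_defuzzify([rule], [strength], lvar)
            assert out == pytest.approx(0.5, abs=1e-9)

    def test_mirror_consequents_with_equal_strengths(self):
        lvar = output_lvar([("Lo", Trapezoid(0.0, 0.0, 0.1, 0.3)),
                            ("Hi", Trapezoid(0.7, 0.9, 1.0, 1.0))])
        rules = [FuzzyRule((("X", "A"),), ("LOut", "Lo")),
                 FuzzyRule((("X", "A"),), ("LOut", "Hi"))]
        out = aggregate_and_defuzzify(rules, [0.6, 0.6], lvar)
        assert out == pytest.approx(0.5, abs=1e-9)

    def test_matches_high_resolution_quadrature(self):
        # centroid of a single clipped trapezoid vs a 10× finer grid
        coarse = output_lvar([("T", Trapezoid(0.1, 0.3, 0.5, 0.9))])
        fine = output_lvar([("T", Trapezoid(0.1, 0.3, 0.5, 0.9))],
                           resolution=10001)
        rule = FuzzyRule((("X", "A"),), ("LOut", "T"))
        a = aggregate_and_defuzzify([rule], [0.55], coarse)
        b = aggregate_and_defuzzify([rule], [0.55], fine)
        assert a == pytest.approx(b, abs=1e-3)

    def test_all_zero_strengths_raise(self):
        lvar = output_lvar([("T", Trapezoid(0, 0, 1, 1))])
        rule = FuzzyRule((("X", "A"),), ("LOut", "T"))
        with pytest.raises(NoRuleFiredError):
            aggregate_and_defuzzify([rule], [0.0], lvar)

    def test_centroid_stays_within_universe(self):
        rng = np.random.default_rng(5)
        lvar = output_lvar([("Lo", Trapezoid(0, 0, 0.2, 0.4)),
                            ("Hi", Trapezoid(0.6, 0.8, 1, 1))])
        rules = [FuzzyRule((("X", "A"),), ("LOut", "Lo")),
                 FuzzyRule((("X", "A"),), ("LOut", "Hi"))]
        for _ in range(100):
            s = rng.uniform(0.01, 1, 2)
            out = aggregate_and_defuzzify(rules, list(s), lvar)
            assert 0.0 <= out <= 1.0


class TestRuleBase:
    def test_expands_to_exactly_nine_rules(self):
        assert len(expand_rule_base(SPINE_RULE_BASE)) == 9

    def test_healthy_corner_maps_to_small_severity(self):
        assert SPINE_RULE_BASE.severity("Small", "High") == "Small"

    def test_diseased_corner_maps_to_high_severity(self):
        assert SPINE_RULE_BASE.severity("High", "Small") == "High"

    def test_incomplete_base_rejected(self):
        with pytest.raises(FuzzyError, match="3×3"):
            expand_rule_base(RuleBase3x3(cells=(("Small",),)))

    def test_non_monotone_base_rejected(self):
        cells = (("High", "Small", "Small"),
                 ("Small", "Medium", "Small"),
                 ("High", "High", "Medium"))
        with pytest.raises(FuzzyError):
            expand_rule_base(RuleBase3x3(cells=cells))


class TestPolicyEvaluation:
    def test_healthy_features_score_below_half(self, fuzzy_policy):
        severity = evaluate_fuzzy_policy(
            fuzzy_policy, {"Amplitude": 1.6, "Width": 105})
        assert 0.0 <= severity < 0.5

    def test_constrained_features_score_above_half(self, fuzzy_policy):
        severity = evaluate_fuzzy_policy(
            fuzzy_policy, {"Amplitude": 0.6, "Width": 300})
        assert 0.5 < severity <= 1.0

    def test_constrained_scores_above_healthy(self, fuzzy_policy):
        s_bad = evaluate_fuzzy_policy(
            fuzzy_policy, {"Amplitude": 0.6, "Width": 300})
        s_ok = evaluate_fuzzy_policy(
            fuzzy_policy, {"Amplitude": 1.6, "Width": 105})
        assert s_bad > s_ok

    def test_unbound_input_rejected(self, fuzzy_policy):
        with pytest.raises(FuzzyError, match="unbound"):
            evaluate_fuzzy_policy(fuzzy_policy, {"Amplitude": 1.6})

    def test_resolution_doubling_converges(self, fuzzy_xml):
        # severity changes by < 1e-3 when the defuzzification grid doubles
        doubled = parse_fuzzy_policy(fuzzy_xml.replace(
            '<Universe lo="0" hi="1"/>',
            '<Universe lo="0" hi="1" resolution="2001"/>'))
        base = parse_fuzzy_policy(fuzzy_xml)
        for bindings in ({"Amplitude": 1.6, "Width": 105},
                         {"Amplitude": 0.6, "Width": 300}):
            a = evaluate_fuzzy_policy(base, bindings)
            b = evaluate_fuzzy_policy(doubled, bindings)
            assert a == pytest.approx(b, abs=1e-3)

    def test_severity_monotone_on_grid(self, fuzzy_policy):
        # nondecreasing in width, nonincreasing in amplitude, within
        # a 0.02 wiggle allowance, on a 41×41 grid
        amplitudes = np.linspace(0, 4, 41)
        widths = np.linspace(0, 400, 41)
        sev = np.array([[evaluate_fuzzy_policy(
            fuzzy_policy, {"Amplitude": float(a), "Width": float(w)})
            for a in amplitudes] for w in widths])
        assert np.diff(sev, axis=1).max() <= 0.02   # amplitude direction
        assert np.diff(sev, axis=0).min() >= -0.02  # width direction


ERROR_CONTROL_EXAMPLE = """
<FuzzyPolicy name="Controller" output="ControlChange">
  <LinguisticVariables>
    <LinguisticVariable name="Error" role="input">
      <Universe lo="-1" hi="1"/>
      <MembershipFunctions>
        <MF Name="Small" Type="Trapezoid" Value="-1,-1,-0.2,0.2"/>
        <MF Name="Large" Type="Trapezoid" Value="-0.2,0.2,1,1"/>
      </MembershipFunctions>
    </LinguisticVariable>
    <LinguisticVariable name="ControlChange" role="output">
      <Universe lo="0" hi="1"/>
      <MembershipFunctions>
        <MF Name="Small" Type="Gaussian" Value="0.2,0.1"/>
        <MF Name="Large" Type="Gaussian" Value="0.8,0.1"/>
      </MembershipFunctions>
    </LinguisticVariable>
  </LinguisticVariables>
  <LVar context="Error" linguistic="Error" direction="fuzzify"/>
  <LVar context="ControlChange" linguistic="ControlChange" direction="defuzzify"/>
  <FuzzyRules>
    <FuzzyRule><If lvar="Error" term="Small"/><Then lvar="ControlChange" term="Small"/></FuzzyRule>
    <FuzzyRule><If lvar="Error" term="Large"/><Then lvar="ControlChange" term="Large"/></FuzzyRule>
  </FuzzyRules>
</FuzzyPolicy>
"""


class TestFuzzyDialect:
    def test_input_and_output_variables_parsed(self):
        policy = parse_fuzzy_policy(ERROR_CONTROL_EXAMPLE)
        assert len(policy.variables) == 2
        assert {v.role for v in policy.variables} == {"input", "output"}

    def test_three_trapezoid_terms(self, fuzzy_policy):
        lvar = fuzzy_policy.variable_map["LAmpl"]
        assert [t.name for t in lvar.terms] == ["Small", "Medium", "High"]
        assert all(isinstance(t.shape, Trapezoid) for t in lvar.terms)

    def test_zero_sigma_gaussian_rejected(self):
        bad = ERROR_CONTROL_EXAMPLE.replace('Value="0.2,0.1"',
                                            'Value="0.2,0"')
        with pytest.raises(PolicySchemaError, match="sigma"):
            parse_fuzzy_policy(bad)

    def test_round_trip(self, fuzzy_xml):
        first = parse_fuzzy_policy(fuzzy_xml)
        second = parse_fuzzy_policy(serialize_fuzzy_policy(first))
        assert first == second
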