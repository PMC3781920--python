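"""Probability algebra, default inputs and validation."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from afcea.parameters import (
    DistributionSpec,
    annual_prob_to_cycle_prob,
    apply_relative_risk,
    cumulative_to_annual_prob,
    cycle_prob_to_annual_prob,
    derive_warfarin_bleed_prob,
    validate_parameters,
)


@pytest.mark.parametrize("p, cl, expected, tol", [
    (0.0, 0.25, 0.0, 0.0),
    (1.0, 0.25, 1.0, 0.0),
    (0.04, 0.25, 0.0101534, 1e-6),  # 1 - 0.96**0.25
])
def test_annual_to_cycle_examples(p, cl, expected, tol):
    assert annual_prob_to_cycle_prob(p, cl) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("p_cum, months, expected, tol", [
    (0.019, 27.54, 0.00832, 5e-5),  # annualised pulmonary-toxicity incidence
    (0.0, 12, 0.0, 0.0),
    (0.5, 12, 0.5, 1e-12),          # identity at a 12-month window
])
def test_cumulative_to_annual_examples(p_cum, months, expected, tol):
    assert cumulative_to_annual_prob(p_cum, months) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("p, rr, expected, tol", [
    (0.04, 0.625, 0.025, 1e-12),    # stroke risk in sinus rhythm
    (0.5, 3.0, 1.0, 0.0),           # capped at certainty
])
def test_apply_relative_risk_examples(p, rr, expected, tol):
    assert apply_relative_risk(p, rr) == pytest.approx(expected, abs=tol)


def test_nsr_after_ablation_matches_published_derivation(params):
    # 2.93 x (unrounded pooled NSR probability) = 0.7554, published as 0.756
    # (consistent with the pooled value carried at three decimals, 0.258)
    assert apply_relative_risk(params.p_nsr_aad_1y, 2.93) == pytest.approx(0.756, abs=1e-3)


@pytest.mark.parametrize("p, rr, expected, tol", [
    (0.0058, 0.45, 0.0129, 1e-4),   # on-warfarin major-bleed probability
    (0.0058, 1.0, 0.0058, 1e-12),
    (0.01, 0.5, 0.02, 1e-12),
])
def test_warfarin_bleed_examples(p, rr, expected, tol):
    assert derive_warfarin_bleed_prob(p, rr) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("func, args", [
    (annual_prob_to_cycle_prob, (1.2, 0.25)),
    (annual_prob_to_cycle_prob, (-0.1, 0.25)),
    (annual_prob_to_cycle_prob, (0.5, 0.0)),
    (cumulative_to_annual_prob, (1.0, 12)),     # infinite rate
    (cumulative_to_annual_prob, (0.5, 0)),
    (apply_relative_risk, (-0.1, 1.0)),
    (apply_relative_risk, (0.5, -1.0)),
    (derive_warfarin_bleed_prob, (0.01, 0.0)),
])
def test_validation_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


@settings(max_examples=200, derandomize=True)
@given(p=st.floats(0.0, 1.0 - 1e-9), cl=st.floats(0.01, 2.0))
def test_annual_cycle_round_trip(p, cl):
    """Cycle conversion inverts, and compounding 1/cl cycles recovers the annual value."""
    pc = annual_prob_to_cycle_prob(p, cl)
    assert cycle_prob_to_annual_prob(pc, cl) == pytest.approx(p, abs=1e-9)
    assert 1.0 - (1.0 - pc) ** (1.0 / cl) == pytest.approx(p, abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(p1=st.floats(0, 1), p2=st.floats(0, 1),
       r1=st.floats(0, 10), r2=st.floats(0, 10))
def test_relative_risk_monotone_and_capped(p1, p2, r1, r2):
    lo_p, hi_p = sorted((p1, p2))
    lo_r, hi_r = sorted((r1, r2))
    assert apply_relative_risk(lo_p, lo_r) <= apply_relative_risk(hi_p, lo_r)
    assert apply_relative_risk(lo_p, lo_r) <= apply_relative_risk(lo_p, hi_r)
    assert apply_relative_risk(hi_p, hi_r) <= 1.0


class TestDefaults:
    def test_key_values(self, params):
        assert params.cost_ablation_total_per_procedure == 9590
        assert params.p_complication_pv_stenosis == 0.016
        assert params.discount_rate == 0.05
        assert params.chads2_stroke_table[2] == 0.04
        assert params.p_bleed_warfarin == pytest.approx(0.0129, abs=1e-4)

    def test_default_set_is_valid(self, params):
        assert validate_parameters(params) == []

    def test_violations_name_the_field(self, params):
        bad = params.replace(p_nsr_aad_1y=1.2)
        violations = validate_parameters(bad)
        assert len(violations) == 1 and violations[0].field == "p_nsr_aad_1y"

        bad = params.replace(cost_gi_bleed=-5.0)
        violations = validate_parameters(bad)
        assert len(violations) == 1 and violations[0].field == "cost_gi_bleed"


class TestDistributionSpec:
    @pytest.mark.parametrize("family, p", [
        ("beta", (0.0, 1.0)),
        ("beta", (1.0,)),
        ("gamma", (-1.0, 2.0)),
        ("lognormal", (0.0, 0.0)),
        ("fixed", (1.0, 2.0)),
        ("triangular", (0.0, 1.0)),
    ])
    def test_invalid_specs_fail_at_build(self, family, p):
        with pytest.raises(ValueError):
            DistributionSpec(family, p)

    def test_means(self):
        assert DistributionSpec("beta", (2.0, 2.0)).mean == 0.5
        assert DistributionSpec("gamma", (25.0, 282.24)).mean == pytest.approx(7056)
        assert DistributionSpec("fixed", (666.0,)).mean == 666.0

    def test_every_default_distribution_targets_a_field(self, params, dists):
        for key in dists:
            if key == "prop_warfarin":
                continue
            base = key.split(".", 1)[0]
            assert hasattr(params, base), key
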