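"""First-year model: branch arithmetic, probability conservation, overlays."""

import dataclasses

import pytest

from afcea.decision_tree import run_first_year
from afcea.markov import AF, NSR
from afcea.parameters import annual_prob_to_cycle_prob


def test_forced_pathway_all_to_sinus_rhythm(no_event_params, profile, immortal_fixtures):
    """With certain rhythm success and no events, everyone enters in NSR."""
    ps = no_event_params.replace(p_nsr_aad_1y=1.0, rr_nsr_ablation=1.0)
    fy = run_first_year("ablation", ps, profile, immortal_fixtures)
    assert fy.deaths == 0.0
    assert fy.entry_distribution == {NSR: pytest.approx(1.0)}


def test_expected_complication_cost_dot_product(no_event_params, profile,
                                                immortal_fixtures):
    """Complication spending equals the hand-computed expected-cost dot product."""
    ps = no_event_params.replace(
        p_complication_stroke=0.003, p_complication_tia=0.002,
        p_complication_tamponade=0.008, p_complication_pv_stenosis=0.016,
        # silence every other cost channel so the total isolates complications
        cost_ablation_hosp=0.0, cost_ablation_md=0.0, cost_ablation_followup_y1=0.0,
        cost_amiodarone_annual=0.0, cost_warfarin_annual=0.0,
        cost_warfarin_monitoring_annual=0.0, cost_ischemic_stroke_y1=0.0,
    )
    fy = run_first_year("ablation", ps, profile, immortal_fixtures)
    oracle = 1.27 * (0.003 * 14872 + 0.002 * 4296 + 0.008 * 5842 + 0.016 * 8487)
    assert fy.cost == pytest.approx(oracle, abs=1e-9)


def test_aad_entry_fraction_closed_form(params, profile, fixtures_bundle):
    """NSR entry equals the rhythm split times four cycles of competing survival."""
    fy = run_first_year("aad", params, profile, fixtures_bundle)
    cl = params.cycle_length
    p_stroke = annual_prob_to_cycle_prob(
        params.chads2_stroke_table[2] / params.rr_stroke_af_vs_nsr, cl)
    bleed = (profile.prop_warfarin * params.p_bleed_warfarin
             + (1 - profile.prop_warfarin) * params.p_bleed_no_warfarin)
    p_ich = annual_prob_to_cycle_prob(bleed, cl) * params.prop_bleed_ich
    p_toxdeath = annual_prob_to_cycle_prob(params.p_pulm_tox_annual, cl) * params.p_pulm_tox_death
    expected = params.p_nsr_aad_1y
    for cycle in range(4):
        age = profile.start_age + cl * cycle
        p_die = annual_prob_to_cycle_prob(
            fixtures_bundle.life_table.annual_death_prob(age, profile.sex), cl)
        expected *= (1 - p_die) * (1 - p_stroke) * (1 - p_ich) * (1 - p_toxdeath)
    assert fy.entry_distribution[NSR] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("strategy", ["ablation", "aad"])
def test_probability_conservation(strategy, params, profile, fixtures_bundle):
    fy = run_first_year(strategy, params, profile, fixtures_bundle)
    assert sum(fy.entry_distribution.values()) + fy.deaths == pytest.approx(1.0, abs=1e-9)
    assert fy.cost >= 0 and 0 <= fy.qaly <= 1


def test_arms_identical_when_strategy_effects_removed(no_event_params,
                                                      fixtures_bundle, profile):
    """No complications, no toxicity, equal rhythm success, no warfarin:
    both arms must reach the Markov model with the same distribution."""
    ps = no_event_params.replace(
        rr_nsr_ablation=1.0, n_procedures=0.0,
        chads2_stroke_table=no_event_params.chads2_stroke_table,
    )
    prof = dataclasses.replace(profile, prop_warfarin=0.0)
    a = run_first_year("ablation", ps, prof, fixtures_bundle)
    b = run_first_year("aad", ps, prof, fixtures_bundle)
    assert set(a.entry_distribution) == set(b.entry_distribution)
    for state, m in a.entry_distribution.items():
        assert m == pytest.approx(b.entry_distribution[state], abs=1e-12)


def test_af_failures_carry_disutility_from_cycle_zero(no_event_params, profile,
                                                      immortal_fixtures):
    """The eventual-failure fraction loses the AF disutility all year."""
    ps = no_event_params.replace(disutility_af=0.1)
    lo = run_first_year("aad", ps, profile, immortal_fixtures)
    hi = run_first_year("aad", ps.replace(disutility_af=0.0), profile,
                        immortal_fixtures)
    af_mass = 1.0 - ps.p_nsr_aad_1y
    assert hi.qaly - lo.qaly == pytest.approx(0.1 * af_mass, abs=1e-9)


def test_unknown_strategy_and_invalid_parameters(params, profile, fixtures_bundle):
    with pytest.raises(ValueError, match="strategy"):
        run_first_year("surgery", params, profile, fixtures_bundle)
    with pytest.raises(ValueError, match="p_nsr_aad_1y"):
        run_first_year("aad", params.replace(p_nsr_aad_1y=1.5), profile,
                       fixtures_bundle)
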