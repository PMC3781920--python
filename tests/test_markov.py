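"""Cohort engine: conservation, closed forms, microsimulation cross-check."""

import numpy as np
import pytest

from afcea import cea
from afcea.decision_tree import run_first_year
from afcea.markov import (
    AF, DEAD, NSR, STATES,
    CohortTrace, accumulate, cycle_transition, cycles_per_year,
    discount_factors, run_markov, simulate_cycles, total_cycles,
)
from afcea.parameters import annual_prob_to_cycle_prob as a2c
from afcea.parameters import cycle_prob_to_annual_prob


def test_dead_is_absorbing(params, profile, fixtures_bundle):
    row = cycle_transition(DEAD, "aad", params, profile, 70.0, fixtures_bundle)
    assert row == {DEAD: 1.0}


def test_nsr_stroke_component_is_chads_rate_over_af_relative_risk(
        params, profile, immortal_fixtures):
    """CHADS2 = 2 gives 0.04/yr in AF; sinus rhythm divides by the 1.6 RR."""
    ps = params.replace(p_bleed_no_warfarin=0.0,
                        rr_bleed_placebo_vs_warfarin=1.0,
                        p_pulm_tox_annual=0.0)
    row = cycle_transition(NSR, "aad", ps, profile, 65.0, immortal_fixtures, cycle=0)
    annual = cycle_prob_to_annual_prob(row["is_y1_0"], ps.cycle_length)
    assert annual == pytest.approx(0.025, abs=1e-12)
    row_af = cycle_transition(AF, "aad", ps, profile, 65.0, immortal_fixtures, cycle=0)
    assert cycle_prob_to_annual_prob(row_af["is_y1_0"], ps.cycle_length) == \
        pytest.approx(0.04, abs=1e-12)


def test_degenerate_af_row(no_event_params, profile, immortal_fixtures):
    row = cycle_transition(AF, "aad", no_event_params, profile, 65.0,
                           immortal_fixtures, cycle=8)
    assert row == {AF: pytest.approx(1.0)}


@pytest.mark.parametrize("strategy", ["ablation", "aad"])
def test_trace_conservation_and_absorbing_death(strategy, params, profile,
                                                fixtures_bundle):
    fy = run_first_year(strategy, params, profile, fixtures_bundle)
    trace = run_markov(fy, strategy, params, profile, fixtures_bundle)
    sums = trace.occupancy.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    dead = trace.occupancy[:, list(STATES).index(DEAD)]
    assert np.all(np.diff(dead) >= -1e-12)
    assert np.all(trace.cost >= 0) and np.all(trace.qaly >= 0)


def test_no_event_cohort_matches_closed_form(no_event_params, profile,
                                             immortal_fixtures):
    """Immortal event-free cohort: occupancy constant, QALYs = discounted
    utility stream, a pure geometric series."""
    ps = no_event_params
    fy = run_first_year("aad", ps, profile, immortal_fixtures)
    trace = run_markov(fy, "aad", ps, profile, immortal_fixtures)
    assert np.allclose(trace.occupancy[-1], trace.occupancy[0])
    res = accumulate(fy, trace, ps, profile)
    u = 0.83
    af_mass = 1.0 - ps.p_nsr_aad_1y
    per_year = u - af_mass * ps.disutility_af
    f = discount_factors(np.arange(total_cycles(ps)), ps)
    expected = per_year * ps.cycle_length * f.sum()
    assert res.expected_qaly == pytest.approx(expected, abs=1e-9)


def test_zero_discount_accumulate_equals_raw_sums(params, profile, fixtures_bundle):
    ps = params.replace(discount_rate=0.0)
    fy = run_first_year("ablation", ps, profile, fixtures_bundle)
    trace = run_markov(fy, "ablation", ps, profile, fixtures_bundle)
    res = accumulate(fy, trace, ps, profile)
    assert res.expected_cost == pytest.approx(fy.cost + trace.cost.sum(), abs=1e-9)
    assert res.expected_qaly == pytest.approx(fy.qaly + trace.qaly.sum(), abs=1e-9)


def test_constant_reward_matches_geometric_series(params, profile):
    """A synthetic trace with constant per-cycle cost discounts to the
    closed-form geometric sum."""
    n = 16
    cycles = np.arange(4, 4 + n)
    r = 100.0
    z = np.zeros(n)
    trace = CohortTrace(cycles=cycles, occupancy=np.zeros((n, len(STATES))),
                        cost=np.full(n, r), qaly=z.copy(), strokes=z.copy(),
                        ich_events=z.copy(), gi_bleeds=z.copy(), tox_cases=z.copy(),
                        deaths=z.copy(), tox_mass=z.copy())

    class _FY:
        strategy = "aad"
        cost = qaly = strokes = ich_events = 0.0

    res = accumulate(_FY(), trace, params, profile)
    q = (1.0 + params.discount_rate) ** (-params.cycle_length)
    geometric = r * q ** 4 * (1 - q ** n) / (1 - q)
    assert res.expected_cost == pytest.approx(geometric, rel=1e-12)


def test_removing_stroke_differential_collapses_stroke_gap(params, profile,
                                                           fixtures_bundle):
    """With no NSR stroke benefit the arms differ only through the procedural
    strokes (plus second-order mortality mixing)."""
    ps = params.replace(rr_stroke_af_vs_nsr=1.0)
    res = cea.compare(
        cea.run_strategy("ablation", ps, profile, fixtures_bundle),
        cea.run_strategy("aad", ps, profile, fixtures_bundle),
    )
    procedural = ps.p_complication_stroke * ps.n_procedures
    assert res.delta_strokes == pytest.approx(procedural, abs=0.003)


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------

def test_cohort_expectation_matches_microsimulation(params, profile,
                                                    fixtures_bundle):
    """8 cycles, 10,000 individuals: cohort expectations within 3 MC SEs."""
    from microsim_oracle import microsimulate

    occ0 = {NSR: 0.6, AF: 0.4}
    n_cycles, n_ind = 8, 10_000
    trace = simulate_cycles(occ0, 0.0, "aad", params, profile, fixtures_bundle,
                            start_cycle=0, n_cycles=n_cycles)
    rng = np.random.default_rng(20130908)
    occ_micro, strokes_micro = microsimulate(
        params, profile, fixtures_bundle, "aad", occ0, n_cycles, n_ind, rng)

    exp_strokes = trace.strokes.sum()
    se_strokes = np.sqrt(exp_strokes / n_ind)  # Poisson-scale error
    assert abs(strokes_micro - exp_strokes) < 3 * se_strokes

    occ_cohort = trace.occupancy[-1]
    for i, s in enumerate(STATES):
        se = np.sqrt(max(occ_cohort[i] * (1 - occ_cohort[i]), 1e-6) / n_ind)
        assert abs(occ_micro[i] - occ_cohort[i]) < 3.5 * se, s
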