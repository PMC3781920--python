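"""Long-term cohort engine: 3-month-cycle Markov model of AF outcomes.

States: normal sinus rhythm (NSR), atrial fibrillation (AF), a four-cycle
tunnel for the first year after ischemic stroke, post-ischemic-stroke later
years, a four-cycle tunnel for the first year after intracranial haemorrhage
(ICH), post-ICH later years, and dead.  Stroke states are permanent: rhythm
(and rhythm-dependent stroke risk) no longer applies after a first stroke,
and recurrent strokes are not modelled.

Each cycle a rhythm-state occupant faces, in order: background death, then
ischemic stroke, then major bleed (split into ICH, which changes state, and
gastrointestinal, which costs but does not), then fatal pulmonary toxicity
(amiodarone-treated occupants only), then AF recurrence.  The ordering is a
modelling convention; at 3-month probabilities its effect is far below the
Monte-Carlo resolution of the validation microsimulation.

Irreversible pulmonary toxicity is tracked as an aggregate prevalence overlay
(a scalar mass scaled by cohort survival each cycle) that replaces the state
utility with the toxicity utility weight and adds the annual toxicity cost.

No half-cycle correction is applied by default; state rewards accrue on the
end-of-cycle occupancy, so an event takes effect — state, cost and utility —
within the cycle it occurs (a counted stroke always carries its stroke
costs).  ``ParameterSet.half_cycle_correction`` switches to averaging start-
and end-of-cycle occupancy for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import FixtureSet
from .parameters import (
    CohortProfile,
    ParameterSet,
    annual_prob_to_cycle_prob as _a2c,
)

__all__ = [
    "NSR", "AF", "IS_LATER", "ICH_LATER", "DEAD", "STATES",
    "CohortTrace", "StrategyResult", "EngineError",
    "cycle_transition", "simulate_cycles", "run_markov", "accumulate",
    "total_cycles", "cycles_per_year",
]

NSR = "nsr"
AF = "af"
IS_LATER = "is_later"
ICH_LATER = "ich_later"
DEAD = "dead"
_IS_TUNNEL = tuple(f"is_y1_{k}" for k in range(4))
_ICH_TUNNEL = tuple(f"ich_y1_{k}" for k in range(4))
STATES: tuple[str, ...] = (NSR, AF) + _IS_TUNNEL + (IS_LATER,) + _ICH_TUNNEL + (ICH_LATER, DEAD)
_IDX = {s: i for i, s in enumerate(STATES)}
_RHYTHM = (NSR, AF)


class EngineError(RuntimeError):
    """Internal consistency failure in the cohort engine."""


def cycles_per_year(ps: ParameterSet) -> int:
    n = round(1.0 / ps.cycle_length)
    if abs(n * ps.cycle_length - 1.0) > 1e-9 or n != 4:
        raise EngineError(
            "the engine's first-year tunnels assume four cycles per year "
            f"(cycle_length = 0.25), got cycle_length = {ps.cycle_length}"
        )
    return n


def total_cycles(ps: ParameterSet) -> int:
    """Total model cycles including the first year."""
    n = round(ps.horizon / ps.cycle_length)
    if not ps.include_first_year_in_horizon:
        n += cycles_per_year(ps)
    return n


# ---------------------------------------------------------------------------
# per-cycle treatment status
# ---------------------------------------------------------------------------

def amiodarone_on(state: str, strategy: str, cycle: int, ps: ParameterSet) -> bool:
    """Whether occupants of ``state`` carry amiodarone cost (and toxicity risk).

    Drug-arm patients take amiodarone in both rhythm states; ablation-arm
    patients only after switching to drug therapy on failure/recurrence
    (i.e. in the AF state, from the start of the second model year).  With
    ``amiodarone_stop_in_af`` set, patients not in NSR stop the drug.
    """
    if state not in _RHYTHM:
        return False
    if strategy == "aad":
        if state == AF and ps.amiodarone_stop_in_af:
            return False
        return True
    # ablation
    if state == AF and cycle >= 4 and not ps.amiodarone_stop_in_af:
        return True
    return False


def warfarin_fraction(
    state: str, strategy: str, cycle: int, ps: ParameterSet, profile: CohortProfile
) -> float:
    """Fraction of the state's occupants on warfarin this cycle.

    Drug-arm rhythm-state patients stay at the cohort proportion throughout.
    Ablation-arm patients discontinue three months after the procedure; those
    who later fail or recur (AF state, second year onward) resume warfarin at
    the cohort proportion.
    """
    if state not in _RHYTHM:
        return 0.0
    if strategy == "aad":
        return profile.prop_warfarin
    if cycle < ps.warfarin_stop_cycle_ablation:
        return profile.prop_warfarin
    if state == AF and cycle >= 4:
        return profile.prop_warfarin
    return 0.0


def _age_rr(table: dict[int, float] | None, age: float) -> float:
    if not table:
        return 1.0
    keys = sorted(table)
    best = keys[0]
    for k in keys:
        if age >= k:
            best = k
    return table[best]


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _transition_with_events(
    state: str,
    strategy: str,
    ps: ParameterSet,
    profile: CohortProfile,
    age: float,
    fixtures: FixtureSet,
    cycle: int,
) -> tuple[dict[str, float], dict[str, float]]:
    cl = ps.cycle_length
    sex = profile.sex
    row: dict[str, float] = {}
    ev = {"stroke": 0.0, "ich": 0.0, "gi_bleed": 0.0, "tox_case": 0.0,
          "tox_irrev_inflow": 0.0}

    if state == DEAD:
        return {DEAD: 1.0}, ev

    q_bg = fixtures.life_table.annual_death_prob(age, sex)

    if state in _IS_TUNNEL:
        q1y = min(fixtures.event_mortality.lookup(age, sex, "ischemic_stroke")
                  * ps.mort_mult_stroke_1y, 0.99)
        p_die = _a2c(q1y, cl)
        k = _IS_TUNNEL.index(state)
        nxt = _IS_TUNNEL[k + 1] if k < 3 else IS_LATER
        return {DEAD: p_die, nxt: 1.0 - p_die}, ev
    if state == IS_LATER:
        p_die = _a2c(min(q_bg * ps.mort_mult_stroke_later, 1.0), cl)
        return {DEAD: p_die, IS_LATER: 1.0 - p_die}, ev
    if state in _ICH_TUNNEL:
        q1y = min(fixtures.event_mortality.lookup(age, sex, "ich")
                  * ps.mort_mult_ich_1y, 0.99)
        p_die = _a2c(q1y, cl)
        k = _ICH_TUNNEL.index(state)
        nxt = _ICH_TUNNEL[k + 1] if k < 3 else ICH_LATER
        return {DEAD: p_die, nxt: 1.0 - p_die}, ev
    if state == ICH_LATER:
        # post-ICH mortality beyond the first year reverts to the population rate
        p_die = _a2c(q_bg, cl)
        return {DEAD: p_die, ICH_LATER: 1.0 - p_die}, ev

    if state not in _RHYTHM:
        raise EngineError(f"unknown state {state!r}")

    # --- rhythm states -----------------------------------------------------
    stroke_annual = ps.chads2_stroke_table[profile.chads2] * _age_rr(ps.rr_stroke_by_age, age)
    if state == NSR:
        stroke_annual /= ps.rr_stroke_af_vs_nsr
    p_stroke = _a2c(min(stroke_annual, 1.0), cl)

    w = warfarin_fraction(state, strategy, cycle, ps, profile)
    bleed_annual = w * ps.p_bleed_warfarin + (1.0 - w) * ps.p_bleed_no_warfarin
    p_bleed = _a2c(min(bleed_annual, 1.0), cl)
    p_ich = p_bleed * ps.prop_bleed_ich
    p_gi = p_bleed - p_ich

    p_tox = _a2c(ps.p_pulm_tox_annual, cl) if amiodarone_on(state, strategy, cycle, ps) else 0.0
    p_rec = 0.0
    if state == NSR and cycle >= 4:
        rate = ps.p_recur_ablation if strategy == "ablation" else ps.p_recur_aad
        p_rec = _a2c(rate, cl)

    p_die = _a2c(q_bg, cl)
    rem = 1.0
    dead = p_die
    rem -= p_die
    flow_stroke = rem * p_stroke
    rem *= 1.0 - p_stroke
    flow_ich = rem * p_ich
    ev["gi_bleed"] = rem * p_gi
    rem *= 1.0 - p_ich
    tox_cases = rem * p_tox
    tox_deaths = tox_cases * ps.p_pulm_tox_death
    dead += tox_deaths
    rem -= tox_deaths
    flow_rec = rem * p_rec
    rem -= flow_rec

    ev["stroke"] = flow_stroke
    ev["ich"] = flow_ich
    ev["tox_case"] = tox_cases
    ev["tox_irrev_inflow"] = (
        tox_cases * (1.0 - ps.p_pulm_tox_death) * ps.prop_pulm_tox_irreversible
    )

    row = {DEAD: dead, _IS_TUNNEL[0]: flow_stroke, _ICH_TUNNEL[0]: flow_ich,
           state: rem}
    if flow_rec:
        row[AF] = row.get(AF, 0.0) + flow_rec
    for s, p in row.items():
        if p < -1e-12:
            raise EngineError(f"negative probability {p} for {state}->{s}")
    return row, ev


def cycle_transition(
    state: str,
    strategy: str,
    ps: ParameterSet,
    profile: CohortProfile,
    age: float,
    fixtures: FixtureSet,
    cycle: int | None = None,
) -> dict[str, float]:
    """One-cycle transition distribution from ``state`` at attained ``age``.

    ``cycle`` (the model cycle index, which controls warfarin/amiodarone
    status and whether recurrence has started) is inferred from the age gap
    to the cohort's starting age when not given.
    """
    if strategy not in ("ablation", "aad"):
        raise ValueError(f"strategy must be 'ablation' or 'aad', got {strategy!r}")
    if cycle is None:
        cycle = round((age - profile.start_age) / ps.cycle_length)
    row, _ = _transition_with_events(state, strategy, ps, profile, age, fixtures, cycle)
    total = sum(row.values())
    if abs(total - 1.0) > 1e-9:
        raise EngineError(f"transition row from {state!r} sums to {total}")
    return {s: p for s, p in row.items() if p > 0.0}


# ---------------------------------------------------------------------------
# cohort propagation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state occupancy plus cost/QALY/event accumulators.

    ``occupancy[i]`` is the end-of-cycle distribution over :data:`STATES`
    after simulating absolute cycle ``cycles[i]``; accumulators are undiscounted
    per-cycle totals.
    """

    cycles: np.ndarray
    occupancy: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    strokes: np.ndarray
    ich_events: np.ndarray
    gi_bleeds: np.ndarray
    tox_cases: np.ndarray
    deaths: np.ndarray
    tox_mass: np.ndarray
    states: tuple[str, ...] = STATES

    @property
    def major_bleeds(self) -> np.ndarray:
        return self.ich_events + self.gi_bleeds

    def occupancy_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", self.cycles)
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.occupancy_frame()
        for name in ("cost", "qaly", "strokes", "ich_events", "gi_bleeds",
                     "tox_cases", "deaths", "tox_mass"):
            df[name] = getattr(self, name)
        df.to_csv(path, index=False)


def _state_utility(state: str, age: float, profile: CohortProfile,
                   ps: ParameterSet, fixtures: FixtureSet) -> float:
    if state == DEAD:
        return 0.0
    if state == NSR:
        return fixtures.utility.utility(age, profile.sex)
    if state == AF:
        return max(0.0, fixtures.utility.utility(age, profile.sex) - ps.disutility_af)
    if state in _IS_TUNNEL or state == IS_LATER:
        return ps.utility_ischemic_stroke
    return ps.utility_ich


def _state_cost_per_cycle(state: str, strategy: str, cycle: int,
                          ps: ParameterSet, profile: CohortProfile) -> float:
    cl = ps.cycle_length
    if state in _IS_TUNNEL:
        return ps.cost_ischemic_stroke_y1 * cl
    if state == IS_LATER:
        return ps.cost_ischemic_stroke_later_annual * cl
    if state in _ICH_TUNNEL:
        return ps.cost_ich_y1 * cl
    if state == ICH_LATER:
        return ps.cost_ich_later_annual * cl
    if state in _RHYTHM:
        c = 0.0
        if amiodarone_on(state, strategy, cycle, ps):
            c += ps.cost_amiodarone_annual * cl
        w = warfarin_fraction(state, strategy, cycle, ps, profile)
        c += w * (ps.cost_warfarin_annual + ps.cost_warfarin_monitoring_annual) * cl
        return c
    return 0.0


def simulate_cycles(
    occ0: dict[str, float] | np.ndarray,
    tox0: float,
    strategy: str,
    ps: ParameterSet,
    profile: CohortProfile,
    fixtures: FixtureSet,
    start_cycle: int,
    n_cycles: int,
) -> CohortTrace:
    """Propagate the cohort for ``n_cycles`` cycles from ``start_cycle``.

    ``occ0`` is the start-of-cycle occupancy (must sum to 1 over all states
    including dead); ``tox0`` the irreversible-toxicity prevalence carried in.
    """
    if isinstance(occ0, dict):
        v = np.zeros(len(STATES))
        for s, m in occ0.items():
            v[_IDX[s]] = m
        occ = v
    else:
        occ = np.asarray(occ0, dtype=float).copy()
    if abs(occ.sum() - 1.0) > 1e-9:
        raise EngineError(f"initial occupancy sums to {occ.sum()}, expected 1")

    cl = ps.cycle_length
    n_states = len(STATES)
    occupancy = np.zeros((n_cycles, n_states))
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    strokes = np.zeros(n_cycles)
    ich_events = np.zeros(n_cycles)
    gi_bleeds = np.zeros(n_cycles)
    tox_cases = np.zeros(n_cycles)
    deaths = np.zeros(n_cycles)
    tox_trace = np.zeros(n_cycles)
    tox = float(tox0)

    for i in range(n_cycles):
        t = start_cycle + i
        age = profile.start_age + cl * t
        new = np.zeros(n_states)
        ev_tot = {"stroke": 0.0, "ich": 0.0, "gi_bleed": 0.0,
                  "tox_case": 0.0, "tox_irrev_inflow": 0.0}
        for idx, s in enumerate(STATES):
            m = occ[idx]
            if m <= 0.0:
                continue
            row, ev = _transition_with_events(s, strategy, ps, profile, age, fixtures, t)
            for s2, p in row.items():
                new[_IDX[s2]] += m * p
            for k2, v2 in ev.items():
                ev_tot[k2] += m * v2
        if abs(new.sum() - occ.sum()) > 1e-9:
            raise EngineError(f"mass not conserved at cycle {t}")

        alive_before = occ.sum() - occ[_IDX[DEAD]]
        alive_after = new.sum() - new[_IDX[DEAD]]
        surv = alive_after / alive_before if alive_before > 0 else 1.0
        tox = min(tox * surv + ev_tot["tox_irrev_inflow"], alive_after)

        occ_r = 0.5 * (occ + new) if ps.half_cycle_correction else new
        c = 0.0
        q = 0.0
        for idx, s in enumerate(STATES):
            m = occ_r[idx]
            if m <= 0.0:
                continue
            c += m * _state_cost_per_cycle(s, strategy, t, ps, profile)
            q += m * _state_utility(s, age, profile, ps, fixtures) * cl
        # irreversible-toxicity overlay (prevalence at cycle start): utility
        # replaced by the toxicity weight, annual toxicity cost added
        u_pop = fixtures.utility.utility(age, profile.sex)
        q += tox * (ps.utility_pulm_tox_irrev - u_pop) * cl
        c += tox * ps.cost_pulm_tox_irrev_annual * cl
        # event one-offs
        c += ev_tot["gi_bleed"] * ps.cost_gi_bleed
        c += ev_tot["tox_case"] * ps.cost_pulm_tox_acute
        q -= ev_tot["tox_case"] * ps.pulm_tox_disutility_days / 365.0

        occupancy[i] = new
        cost[i] = c
        qaly[i] = max(q, 0.0)
        strokes[i] = ev_tot["stroke"]
        ich_events[i] = ev_tot["ich"]
        gi_bleeds[i] = ev_tot["gi_bleed"]
        tox_cases[i] = ev_tot["tox_case"]
        deaths[i] = new[_IDX[DEAD]] - occ[_IDX[DEAD]]
        tox_trace[i] = tox
        occ = new

    return CohortTrace(
        cycles=np.arange(start_cycle, start_cycle + n_cycles),
        occupancy=occupancy, cost=cost, qaly=qaly, strokes=strokes,
        ich_events=ich_events, gi_bleeds=gi_bleeds, tox_cases=tox_cases,
        deaths=deaths, tox_mass=tox_trace,
    )


# ---------------------------------------------------------------------------
# long-term run and discounted accumulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyResult:
    """Discounted expected cost and QALYs plus undiscounted event counts."""

    expected_cost: float
    expected_qaly: float
    expected_strokes: float
    expected_ich: float
    settings: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("expected_cost", "expected_qaly", "expected_strokes", "expected_ich"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


def run_markov(entry, strategy: str, ps: ParameterSet, profile: CohortProfile,
               fixtures: FixtureSet) -> CohortTrace:
    """Continue the cohort from the end of the first model year to the horizon.

    ``entry`` is a :class:`~afcea.decision_tree.FirstYearResult`; its entry
    distribution (alive states) plus first-year deaths seed the occupancy.
    """
    cpy = cycles_per_year(ps)
    n_markov = total_cycles(ps) - cpy
    if n_markov < 0:
        raise ValueError("horizon shorter than the first model year")
    occ0 = {DEAD: entry.deaths}
    for s, m in entry.entry_distribution.items():
        occ0[s] = occ0.get(s, 0.0) + m
    return simulate_cycles(occ0, entry.tox_mass, strategy, ps, profile,
                           fixtures, start_cycle=cpy, n_cycles=n_markov)


def discount_factors(cycles: np.ndarray, ps: ParameterSet) -> np.ndarray:
    """Per-cycle discount factors; the first model year is undiscounted."""
    t_years = cycles * ps.cycle_length
    f = (1.0 + ps.discount_rate) ** (-t_years)
    f[cycles < cycles_per_year(ps)] = 1.0
    return f


def accumulate(first_year, trace: CohortTrace, ps: ParameterSet,
               profile: CohortProfile | None = None) -> StrategyResult:
    """Discounted totals across the first year and the Markov trace.

    Costs and QALYs are discounted at the annual rate (first-year amounts
    undiscounted); stroke and ICH counts are undiscounted expectations.
    """
    f = discount_factors(trace.cycles, ps)
    settings = {
        "strategy": getattr(first_year, "strategy", None),
        "horizon": ps.horizon,
        "discount_rate": ps.discount_rate,
        "include_first_year_in_horizon": ps.include_first_year_in_horizon,
    }
    if profile is not None:
        settings.update(start_age=profile.start_age, sex=profile.sex,
                        chads2=profile.chads2)
    return StrategyResult(
        expected_cost=first_year.cost + float(np.sum(f * trace.cost)),
        expected_qaly=first_year.qaly + float(np.sum(f * trace.qaly)),
        expected_strokes=first_year.strokes + float(np.sum(trace.strokes)),
        expected_ich=first_year.ich_events + float(np.sum(trace.ich_events)),
        settings=settings,
    )
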