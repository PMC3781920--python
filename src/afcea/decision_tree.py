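"""First model year: procedure, complications, toxicity and rhythm outcome.

The first year is simulated with the same cycle machinery as the long-term
model (four 3-month cycles) under strategy-specific overlays:

* **Ablation** — procedure and first-year follow-up costs at cycle 0;
  per-procedure complication probabilities scaled by the expected number of
  procedures; procedural strokes enter the first-year stroke tunnel
  permanently; non-stroke complications (TIA, tamponade, PV stenosis) incur
  a one-off cost and seven days of full disutility; warfarin is carried for
  the first cycle only; no amiodarone.
* **Drug therapy (aad)** — amiodarone, warfarin and monitoring costs all
  year; pulmonary-toxicity risk from cycle 0.

The 12-month rhythm outcome (probability of sinus rhythm: the pooled drug
value, times the ablation relative risk for the ablation arm) is applied as
the cycle-0 split, so stroke, bleed and mortality risk accrue throughout the
first year and the AF disutility applies to the eventual-failure fraction
from the start.  Recurrence dynamics begin only after the first year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fixtures import FixtureSet
from .markov import (
    AF, DEAD, NSR, STATES, CohortTrace, EngineError,
    cycles_per_year, simulate_cycles,
)
from .parameters import CohortProfile, ParameterSet, validate_parameters

__all__ = ["FirstYearResult", "run_first_year"]

_IS_T0 = "is_y1_0"


@dataclass(frozen=True)
class FirstYearResult:
    """Outcome of the one-year short-term model.

    ``entry_distribution`` maps alive Markov states to probabilities;
    together with ``deaths`` it sums to 1.  ``tox_mass`` is the fraction with
    irreversible pulmonary toxicity carried into the long-term model.
    """

    strategy: str
    cost: float
    qaly: float
    strokes: float
    ich_events: float
    deaths: float
    entry_distribution: dict[str, float]
    tox_mass: float
    trace: CohortTrace = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        total = sum(self.entry_distribution.values()) + self.deaths
        if abs(total - 1.0) > 1e-9:
            raise EngineError(
                f"entry distribution plus deaths sums to {total}, expected 1"
            )


def run_first_year(
    strategy: str,
    ps: ParameterSet,
    profile: CohortProfile,
    fixtures: FixtureSet,
) -> FirstYearResult:
    """Run the one-year short-term model for one strategy.

    Raises ``ValueError`` on an unknown strategy or an invalid parameter set.
    """
    if strategy not in ("ablation", "aad"):
        raise ValueError(f"strategy must be 'ablation' or 'aad', got {strategy!r}")
    violations = validate_parameters(ps)
    if violations:
        raise ValueError(
            "invalid parameters: " + "; ".join(str(v) for v in violations)
        )

    one_off_cost = 0.0
    one_off_qaly = 0.0
    procedural_strokes = 0.0
    occ0 = dict.fromkeys(STATES, 0.0)

    if strategy == "ablation":
        p_nsr = ps.p_nsr_ablation_1y
        scale = ps.n_procedures if ps.scale_complications_by_procedures else 1.0
        p_proc_stroke = min(ps.p_complication_stroke * scale, 1.0)
        p_nonstroke = min(
            (ps.p_complication_tia + ps.p_complication_tamponade
             + ps.p_complication_pv_stenosis) * scale, 1.0)

        one_off_cost += ps.cost_ablation_total_per_procedure * ps.n_procedures
        one_off_cost += ps.cost_ablation_followup_y1
        one_off_cost += scale * (
            ps.p_complication_stroke * ps.cost_complication_stroke
            + ps.p_complication_tia * ps.cost_complication_tia
            + ps.p_complication_tamponade * ps.cost_complication_tamponade
            + ps.p_complication_pv_stenosis * ps.cost_complication_pv_stenosis
        )
        one_off_qaly -= p_nonstroke * ps.complication_disutility_days / 365.0
        # procedural strokes are seeded at the start of cycle 0 rather than
        # occurring as an in-cycle event, so they traverse only three tunnel
        # rewards before reaching the later-years state; one quarter of the
        # first-year/later cost difference restores a full year of stroke cost
        one_off_cost += p_proc_stroke * (
            ps.cost_ischemic_stroke_y1 - ps.cost_ischemic_stroke_later_annual
        ) * ps.cycle_length

        occ0[_IS_T0] = p_proc_stroke
        procedural_strokes = p_proc_stroke
        rem = 1.0 - p_proc_stroke
    else:
        p_nsr = ps.p_nsr_aad_1y
        rem = 1.0

    occ0[NSR] = rem * p_nsr
    occ0[AF] = rem * (1.0 - p_nsr)

    cpy = cycles_per_year(ps)
    trace = simulate_cycles(occ0, 0.0, strategy, ps, profile, fixtures,
                            start_cycle=0, n_cycles=cpy)

    final = trace.occupancy[-1]
    idx = {s: i for i, s in enumerate(STATES)}
    entry = {s: float(final[idx[s]]) for s in STATES
             if s != DEAD and final[idx[s]] > 0.0}
    deaths = float(final[idx[DEAD]])

    return FirstYearResult(
        strategy=strategy,
        cost=one_off_cost + float(trace.cost.sum()),
        qaly=max(0.0, float(trace.qaly.sum()) + one_off_qaly),
        strokes=procedural_strokes + float(trace.strokes.sum()),
        ich_events=float(trace.ich_events.sum()),
        deaths=deaths,
        entry_distribution=entry,
        tox_mass=float(trace.tox_mass[-1]),
        trace=trace,
    )
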