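"""Individual-level brute-force oracle for the cohort engine.

Simulates the documented per-cycle event order (background death, ischemic
stroke, ICH, pulmonary-toxicity death, AF recurrence) with independent
Bernoulli draws per individual.  Written directly against the model
description so it validates the engine's competing-risk composition, not
just its bookkeeping.
"""

import numpy as np

from afcea.markov import AF, DEAD, NSR, STATES
from afcea.parameters import annual_prob_to_cycle_prob as a2c


def microsimulate(ps, profile, fixtures, strategy, occ0, n_cycles, n_ind, rng):
    """Return (final state occupancy, expected strokes per individual)."""
    cl = ps.cycle_length
    state_ids = {s: i for i, s in enumerate(STATES)}
    states = rng.choice(len(STATES), size=n_ind,
                        p=[occ0.get(s, 0.0) for s in STATES])
    strokes = np.zeros(n_ind)
    is_tunnel = [state_ids[f"is_y1_{k}"] for k in range(4)]
    ich_tunnel = [state_ids[f"ich_y1_{k}"] for k in range(4)]

    for cycle in range(n_cycles):
        age = profile.start_age + cl * cycle
        q_bg = fixtures.life_table.annual_death_prob(age, profile.sex)
        u = rng.random((n_ind, 5))
        new = states.copy()
        for rhythm, sid in ((NSR, state_ids[NSR]), (AF, state_ids[AF])):
            sel = states == sid
            if not sel.any():
                continue
            p_die = a2c(q_bg, cl)
            rate = ps.chads2_stroke_table[profile.chads2]
            if rhythm == NSR:
                rate /= ps.rr_stroke_af_vs_nsr
            p_stroke = a2c(rate, cl)
            if strategy == "aad":
                w = profile.prop_warfarin
            else:
                w = profile.prop_warfarin if (
                    cycle < ps.warfarin_stop_cycle_ablation
                    or (rhythm == AF and cycle >= 4)) else 0.0
            p_bleed = a2c(w * ps.p_bleed_warfarin
                          + (1 - w) * ps.p_bleed_no_warfarin, cl)
            p_ich = p_bleed * ps.prop_bleed_ich
            on_amio = (strategy == "aad") or (rhythm == AF and cycle >= 4)
            p_toxdeath = (a2c(ps.p_pulm_tox_annual, cl) * ps.p_pulm_tox_death
                          if on_amio else 0.0)
            p_rec = 0.0
            if rhythm == NSR and cycle >= 4:
                p_rec = a2c(ps.p_recur_ablation if strategy == "ablation"
                            else ps.p_recur_aad, cl)

            die = sel & (u[:, 0] < p_die)
            alive = sel & ~die
            stroke = alive & (u[:, 1] < p_stroke)
            rest = alive & ~stroke
            ich = rest & (u[:, 2] < p_ich)
            rest = rest & ~ich
            toxdie = rest & (u[:, 3] < p_toxdeath)
            rest = rest & ~toxdie
            recur = rest & (u[:, 4] < p_rec)
            new[die | toxdie] = state_ids[DEAD]
            new[stroke] = is_tunnel[0]
            strokes[stroke] += 1
            new[ich] = ich_tunnel[0]
            new[recur] = state_ids[AF]
        for k, sid in enumerate(is_tunnel):
            sel = states == sid
            if not sel.any():
                continue
            q1y = min(fixtures.event_mortality.lookup(age, profile.sex,
                                                      "ischemic_stroke")
                      * ps.mort_mult_stroke_1y, 0.99)
            die = sel & (u[:, 0] < a2c(q1y, cl))
            new[die] = state_ids[DEAD]
            new[sel & ~die] = is_tunnel[k + 1] if k < 3 else state_ids["is_later"]
        sel = states == state_ids["is_later"]
        if sel.any():
            die = sel & (u[:, 0] < a2c(min(q_bg * ps.mort_mult_stroke_later, 1.0), cl))
            new[die] = state_ids[DEAD]
        for k, sid in enumerate(ich_tunnel):
            sel = states == sid
            if not sel.any():
                continue
            q1y = min(fixtures.event_mortality.lookup(age, profile.sex, "ich")
                      * ps.mort_mult_ich_1y, 0.99)
            die = sel & (u[:, 0] < a2c(q1y, cl))
            new[die] = state_ids[DEAD]
            new[sel & ~die] = ich_tunnel[k + 1] if k < 3 else state_ids["ich_later"]
        sel = states == state_ids["ich_later"]
        if sel.any():
            die = sel & (u[:, 0] < a2c(q_bg, cl))
            new[die] = state_ids[DEAD]
        states = new
    occ = np.bincount(states, minlength=len(STATES)) / n_ind
    return occ, strokes.sum() / n_ind
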