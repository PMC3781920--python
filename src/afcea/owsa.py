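"""One-way and scenario sensitivity analysis.

A scenario is a named patch on the basecase: parameter fields
(``params.<field>``, including ``params.chads2_stroke_table.<score>``) and
cohort fields (``profile.<field>``).  Each scenario deterministically
re-runs both arms and reports incremental cost, QALYs, strokes and the
ICER or dominance label.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace

import pandas as pd

from .cea import compare, run_strategy
from .fixtures import FixtureSet, default_fixtures
from .parameters import CohortProfile, ParameterSet, build_default_parameters

__all__ = ["ScenarioSpec", "apply_overrides", "builtin_scenarios", "run_scenarios"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of overrides applied on top of the basecase inputs."""

    name: str
    overrides: dict


_PARAM_FIELDS = {f.name for f in dc_fields(ParameterSet)}
_PROFILE_FIELDS = {f.name for f in dc_fields(CohortProfile)}


def apply_overrides(
    overrides: dict, ps: ParameterSet, profile: CohortProfile
) -> tuple[ParameterSet, CohortProfile]:
    """Apply dotted-path overrides; unknown fields raise with the valid names."""
    p_changes: dict = {}
    prof_changes: dict = {}
    table = None
    for key, value in overrides.items():
        parts = key.split(".")
        if parts[0] == "params" and len(parts) >= 2:
            name = parts[1]
            if name == "chads2_stroke_table" and len(parts) == 3:
                if table is None:
                    table = dict(ps.chads2_stroke_table)
                table[int(parts[2])] = float(value)
                continue
            if name not in _PARAM_FIELDS:
                raise ValueError(
                    f"unknown parameter field {name!r}; valid fields: "
                    f"{sorted(_PARAM_FIELDS)}"
                )
            p_changes[name] = value
        elif parts[0] == "profile" and len(parts) == 2:
            name = parts[1]
            if name not in _PROFILE_FIELDS:
                raise ValueError(
                    f"unknown profile field {name!r}; valid fields: "
                    f"{sorted(_PROFILE_FIELDS)}"
                )
            prof_changes[name] = value
        else:
            raise ValueError(
                f"override key {key!r} must look like 'params.<field>' or "
                "'profile.<field>'"
            )
    if table is not None:
        p_changes["chads2_stroke_table"] = table
    new_ps = ps.replace(**p_changes) if p_changes else ps
    new_profile = replace(profile, **prof_changes) if prof_changes else profile
    return new_ps, new_profile


def builtin_scenarios() -> list[ScenarioSpec]:
    """The shipped sensitivity grid.

    Age/sex scenarios move only the life-table and utility lookups (stroke
    risk held at the profile's CHADS2 value for every starting age); the
    age-varying stroke-risk alternative is available through the
    ``params.rr_stroke_by_age`` hook but ships no values.
    """
    specs: list[ScenarioSpec] = [ScenarioSpec("basecase", {})]
    for sex in ("male", "female"):
        for age in (55, 60, 65, 70, 75):
            specs.append(ScenarioSpec(
                f"age_{age}_{sex}",
                {"profile.start_age": age, "profile.sex": sex},
            ))
    for score in range(5):
        specs.append(ScenarioSpec(f"chads2_{score}", {"profile.chads2": score}))
    for years in (3, 5, 10, 20):
        specs.append(ScenarioSpec(f"horizon_{years}y", {"params.horizon": float(years)}))
    for rate in (0.0, 0.03, 0.05):
        specs.append(ScenarioSpec(
            f"discount_{int(rate * 100)}pct", {"params.discount_rate": rate}))
    specs.append(ScenarioSpec(
        "no_nsr_stroke_benefit", {"params.rr_stroke_af_vs_nsr": 1.0}))
    for d in (0.0, 0.02, 0.04, 0.06, 0.08):
        specs.append(ScenarioSpec(
            f"af_disutility_{d:.2f}", {"params.disutility_af": d}))
    for r in (0.0, 0.01, 0.02, 0.03, 0.04, 0.05):
        specs.append(ScenarioSpec(
            f"ablation_recurrence_{r:.2f}", {"params.p_recur_ablation": r}))
    specs.append(ScenarioSpec(
        "amiodarone_stopped_in_af", {"params.amiodarone_stop_in_af": True}))
    return specs


def run_scenarios(
    specs: list[ScenarioSpec],
    fixtures: FixtureSet | None = None,
    ps: ParameterSet | None = None,
    profile: CohortProfile | None = None,
) -> pd.DataFrame:
    """Run every scenario; returns one row per scenario.

    Columns: scenario name, per-arm expected cost/QALYs, incremental cost,
    QALYs and strokes, and ``icer`` (a number, or the dominance label).
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate scenario names: {dupes}")
    if fixtures is None:
        fixtures = default_fixtures()
    if ps is None:
        ps, _ = build_default_parameters()
    if profile is None:
        profile = CohortProfile()

    rows = []
    for spec in specs:
        ps_i, prof_i = apply_overrides(spec.overrides, ps, profile)
        res = compare(
            run_strategy("ablation", ps_i, prof_i, fixtures),
            run_strategy("aad", ps_i, prof_i, fixtures),
        )
        rows.append({
            "name": spec.name,
            "ablation_cost": res.ablation.expected_cost,
            "ablation_qaly": res.ablation.expected_qaly,
            "aad_cost": res.aad.expected_cost,
            "aad_qaly": res.aad.expected_qaly,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "delta_strokes": res.delta_strokes,
            "icer": res.icer if res.icer is not None else res.label,
        })
    return pd.DataFrame(rows, columns=[
        "name", "ablation_cost", "ablation_qaly", "aad_cost", "aad_qaly",
        "delta_cost", "delta_qaly", "delta_strokes", "icer",
    ])
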