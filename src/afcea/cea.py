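"""Incremental cost-effectiveness comparison of the two strategies."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import decision_tree, markov
from .fixtures import FixtureSet, default_fixtures
from .markov import StrategyResult
from .parameters import CohortProfile, ParameterSet, build_default_parameters

__all__ = ["CEResult", "compare", "run_strategy", "run_basecase"]


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison (ablation minus drug therapy).

    ``icer`` is the incremental cost per QALY when both deltas point the same
    way; otherwise ``label`` records dominance ("dominates": ablation cheaper
    and more effective, "dominated": the reverse) or "undefined" when the
    QALY delta is zero.
    """

    ablation: StrategyResult
    aad: StrategyResult
    delta_cost: float
    delta_qaly: float
    delta_strokes: float
    delta_ich: float
    icer: float | None
    label: str

    def summary(self) -> str:
        icer = f"${self.icer:,.0f}/QALY" if self.icer is not None else self.label
        return (
            f"ablation: cost ${self.ablation.expected_cost:,.0f}, "
            f"QALYs {self.ablation.expected_qaly:.3f}, "
            f"strokes {self.ablation.expected_strokes:.3f}\n"
            f"aad:      cost ${self.aad.expected_cost:,.0f}, "
            f"QALYs {self.aad.expected_qaly:.3f}, "
            f"strokes {self.aad.expected_strokes:.3f}\n"
            f"incremental: cost ${self.delta_cost:,.0f}, "
            f"QALYs {self.delta_qaly:.3f}, strokes {self.delta_strokes:.3f}, "
            f"{icer}"
        )

    def to_dict(self) -> dict:
        return {
            "ablation": {"cost": self.ablation.expected_cost,
                         "qaly": self.ablation.expected_qaly,
                         "strokes": self.ablation.expected_strokes,
                         "ich": self.ablation.expected_ich},
            "aad": {"cost": self.aad.expected_cost,
                    "qaly": self.aad.expected_qaly,
                    "strokes": self.aad.expected_strokes,
                    "ich": self.aad.expected_ich},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_strokes": self.delta_strokes,
            "delta_ich": self.delta_ich,
            "icer": self.icer,
            "label": self.label,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy": "ablation", "expected_cost": self.ablation.expected_cost,
             "expected_strokes": self.ablation.expected_strokes,
             "expected_qaly": self.ablation.expected_qaly},
            {"strategy": "aad", "expected_cost": self.aad.expected_cost,
             "expected_strokes": self.aad.expected_strokes,
             "expected_qaly": self.aad.expected_qaly},
            {"strategy": "incremental", "expected_cost": self.delta_cost,
             "expected_strokes": self.delta_strokes,
             "expected_qaly": self.delta_qaly,
             "icer": self.icer if self.icer is not None else self.label},
        ]
        return pd.DataFrame(rows)


def compare(ablation: StrategyResult, aad: StrategyResult) -> CEResult:
    """Incremental values (ablation − drug therapy) with dominance handling.

    Raises ``ValueError`` if the two results were produced under different
    profile/horizon/discount settings.
    """
    sa = {k: v for k, v in ablation.settings.items() if k != "strategy"}
    sb = {k: v for k, v in aad.settings.items() if k != "strategy"}
    if sa and sb and sa != sb:
        raise ValueError(f"mismatched settings: {sa} vs {sb}")

    dc = ablation.expected_cost - aad.expected_cost
    dq = ablation.expected_qaly - aad.expected_qaly
    ds = ablation.expected_strokes - aad.expected_strokes
    di = ablation.expected_ich - aad.expected_ich

    if dq == 0.0:
        icer, label = None, "undefined"
    elif dc < 0.0 and dq > 0.0:
        icer, label = None, "dominates"
    elif dc > 0.0 and dq < 0.0:
        icer, label = None, "dominated"
    else:
        icer, label = dc / dq, "icer"
    return CEResult(ablation=ablation, aad=aad, delta_cost=dc, delta_qaly=dq,
                    delta_strokes=ds, delta_ich=di, icer=icer, label=label)


def run_strategy(strategy: str, ps: ParameterSet, profile: CohortProfile,
                 fixtures: FixtureSet) -> StrategyResult:
    """Full pipeline for one arm: first year, long-term cohort, discounting."""
    fy = decision_tree.run_first_year(strategy, ps, profile, fixtures)
    trace = markov.run_markov(fy, strategy, ps, profile, fixtures)
    return markov.accumulate(fy, trace, ps, profile)


def run_basecase(
    ps: ParameterSet | None = None,
    profile: CohortProfile | None = None,
    fixtures: FixtureSet | None = None,
) -> CEResult:
    """Deterministic basecase comparison with default inputs where omitted."""
    if ps is None:
        ps, _ = build_default_parameters()
    if profile is None:
        profile = CohortProfile()
    if fixtures is None:
        fixtures = default_fixtures()
    return compare(
        run_strategy("ablation", ps, profile, fixtures),
        run_strategy("aad", ps, profile, fixtures),
    )
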