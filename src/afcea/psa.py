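"""Probabilistic sensitivity analysis and acceptability curves.

Each Monte-Carlo draw samples every uncertain parameter independently from
its distribution (probabilities from betas, costs from gammas, relative
risks from lognormals; fixed parameters untouched), re-runs both strategies
deterministically, and records the incremental cost/QALY pair.  The
cost-effectiveness acceptability curve (CEAC) applies the net-monetary-
benefit rule: at willingness-to-pay λ, ablation is preferred in a draw when
``λ·ΔQALY − ΔCost > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import run_strategy
from .fixtures import FixtureSet, default_fixtures
from .parameters import (
    CohortProfile,
    ParameterSet,
    DistributionSpec,
    build_default_parameters,
)

__all__ = ["PSADraw", "CEACCurve", "sample_parameter_set", "run_psa",
           "ceac", "draws_frame", "plot_ceac"]


@dataclass(frozen=True)
class PSADraw:
    """One Monte-Carlo draw: sampled inputs and per-strategy outcomes."""

    index: int
    params: ParameterSet
    profile: CohortProfile
    ablation_cost: float
    ablation_qaly: float
    aad_cost: float
    aad_qaly: float

    @property
    def delta_cost(self) -> float:
        return self.ablation_cost - self.aad_cost

    @property
    def delta_qaly(self) -> float:
        return self.ablation_qaly - self.aad_qaly


@dataclass(frozen=True)
class CEACCurve:
    """Probability that ablation is cost-effective along a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def sample_parameter_set(
    base_ps: ParameterSet,
    base_profile: CohortProfile,
    dists: dict[str, DistributionSpec],
    rng: np.random.Generator,
) -> tuple[ParameterSet, CohortProfile]:
    """Draw one parameter set (and cohort profile) from the distribution map.

    Keys are :class:`ParameterSet` field names, ``"chads2_stroke_table.<score>"``
    for an entry of the stroke table, or ``"prop_warfarin"`` for the profile.
    Keys are sampled in sorted order so a seeded generator reproduces draws.
    """
    changes: dict[str, object] = {}
    prof_changes: dict[str, object] = {}
    table = None
    for key in sorted(dists):
        spec = dists[key]
        value = float(spec.sample(rng))
        if key == "prop_warfarin":
            prof_changes["prop_warfarin"] = value
        elif key.startswith("chads2_stroke_table."):
            score = int(key.split(".", 1)[1])
            if table is None:
                table = dict(base_ps.chads2_stroke_table)
            table[score] = value
        elif hasattr(base_ps, key):
            changes[key] = value
        else:
            raise KeyError(f"distribution key {key!r} matches no parameter field")
    if table is not None:
        changes["chads2_stroke_table"] = table
    ps = base_ps.replace(**changes) if changes else base_ps
    profile = replace(base_profile, **prof_changes) if prof_changes else base_profile
    return ps, profile


def run_psa(
    n_draws: int,
    seed: int,
    profile: CohortProfile | None = None,
    fixtures: FixtureSet | None = None,
    ps: ParameterSet | None = None,
    dists: dict[str, DistributionSpec] | None = None,
) -> list[PSADraw]:
    """Run the probabilistic sensitivity analysis; reproducible given ``seed``."""
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if profile is None:
        profile = CohortProfile()
    if fixtures is None:
        fixtures = default_fixtures()
    if ps is None or dists is None:
        base_ps, base_dists = build_default_parameters()
        ps = ps if ps is not None else base_ps
        dists = dists if dists is not None else base_dists

    rng = np.random.default_rng(seed)
    draws: list[PSADraw] = []
    for i in range(n_draws):
        ps_i, prof_i = sample_parameter_set(ps, profile, dists, rng)
        abl = run_strategy("ablation", ps_i, prof_i, fixtures)
        aad = run_strategy("aad", ps_i, prof_i, fixtures)
        draws.append(PSADraw(
            index=i, params=ps_i, profile=prof_i,
            ablation_cost=abl.expected_cost, ablation_qaly=abl.expected_qaly,
            aad_cost=aad.expected_cost, aad_qaly=aad.expected_qaly,
        ))
    return draws


def ceac(draws: list[PSADraw], wtp_grid) -> CEACCurve:
    """Acceptability curve by the net-monetary-benefit rule.

    At λ = 0 the curve equals the fraction of draws in which ablation is
    cheaper; as λ grows it approaches the fraction in which ablation gains
    QALYs.
    """
    if not draws:
        raise ValueError("at least one draw is required")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    prob = np.array([np.mean(lam * dq - dc > 0.0) for lam in wtp])
    return CEACCurve(wtp=wtp, probability=prob)


def draws_frame(draws: list[PSADraw]) -> pd.DataFrame:
    return pd.DataFrame({
        "draw": [d.index for d in draws],
        "ablation_cost": [d.ablation_cost for d in draws],
        "ablation_qaly": [d.ablation_qaly for d in draws],
        "aad_cost": [d.aad_cost for d in draws],
        "aad_qaly": [d.aad_qaly for d in draws],
        "delta_cost": [d.delta_cost for d in draws],
        "delta_qaly": [d.delta_qaly for d in draws],
    })


def plot_ceac(curve: CEACCurve, path) -> None:
    """Write the acceptability curve to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(ablation cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
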