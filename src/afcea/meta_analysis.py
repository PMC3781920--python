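"""Random-effects pooling of 12-month sinus-rhythm proportions.

The comparator arm's probability of being in normal sinus rhythm (NSR) one
year after starting a second-line antiarrhythmic drug is estimated by pooling
the drug arms of five randomized trials with DerSimonian–Laird random-effects
meta-analysis on the *untransformed* proportion scale, using the binomial
within-study variance ``p(1-p)/n``.  This scale reproduces both the published
pooled value (0.26, 95% CI 0.17–0.34) and the published per-study weights.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StudyArm", "PooledEstimate", "pool_proportions",
           "load_study_arms", "load_default_study_arms"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class StudyArm:
    """One trial arm: patients at risk and patients in NSR at 12 months."""

    label: str
    n: int
    events: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.label}: n must be positive, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise ValueError(
                f"{self.label}: events must be in 0..n, got {self.events}/{self.n}"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.n


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    weights: tuple[float, ...]   # normalized random-effects weights
    tau2: float                  # between-study variance


def _continuity_adjusted(arm: StudyArm) -> float:
    # boundary counts get 0.5/(n+1) pulled off the edge so the binomial
    # variance is non-degenerate; interior counts are untouched
    if arm.events == 0:
        return 0.5 / (arm.n + 1)
    if arm.events == arm.n:
        return 1.0 - 0.5 / (arm.n + 1)
    return arm.proportion


def pool_proportions(studies: list[StudyArm]) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooled proportion with 95% CI.

    With a single study the estimate is that study's proportion with
    ``tau2 = 0``; with identical proportions the random-effects weights
    coincide with the fixed-effect inverse-variance weights.
    """
    if not studies:
        raise ValueError("at least one study is required")
    p = np.array([_continuity_adjusted(s) for s in studies], dtype=float)
    n = np.array([s.n for s in studies], dtype=float)
    v = p * (1.0 - p) / n

    w_fixed = 1.0 / v
    p_fixed = float(np.sum(w_fixed * p) / np.sum(w_fixed))
    k = len(studies)
    if k == 1:
        tau2 = 0.0
    else:
        q = float(np.sum(w_fixed * (p - p_fixed) ** 2))
        c = float(np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed))
        tau2 = max(0.0, (q - (k - 1)) / c)

    w = 1.0 / (v + tau2)
    est = float(np.sum(w * p) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return PooledEstimate(
        estimate=est,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        weights=tuple(w / np.sum(w)),
        tau2=tau2,
    )


def load_study_arms(path: str | Path) -> list[StudyArm]:
    """Read study arms from a delimited table with columns label, n, events."""
    df = pd.read_csv(path)
    missing = {"label", "n", "events"} - set(df.columns)
    if missing:
        raise ValueError(f"study table is missing columns: {sorted(missing)}")
    return [StudyArm(str(r.label), int(r.n), int(r.events)) for r in df.itertuples()]


def load_default_study_arms() -> list[StudyArm]:
    """The five shipped AAD trial arms (12-month NSR counts)."""
    ref = importlib.resources.files("afcea.data") / "nsr_trials_12m.csv"
    with importlib.resources.as_file(ref) as path:
        return load_study_arms(path)
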