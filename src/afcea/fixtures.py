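"""Synthetic stand-in tables for external population inputs.

The model needs three external tables that are not part of this package's
printed inputs: an age/sex life table, age/sex 28–30-day case-fatality after
ischemic stroke and intracranial haemorrhage (ICH), and age/sex general-
population utilities.  This module generates deterministic parametric
stand-ins with the right statistical structure (SYNTHETIC fixtures, not the
copyrighted source tables), and loads user-supplied replacements from
delimited text files in the same schema so real registry/statistical-agency
values can be dropped in.

Schemas (CSV):
  life table / utilities: ``age,sex,value``
  event mortality:        ``age,sex,event,value`` (age = band lower bound,
                          event in {ischemic_stroke, ich})
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import math

import pandas as pd

__all__ = [
    "LifeTable", "EventMortalityTable", "UtilityTable", "FixtureSet",
    "make_life_table", "make_event_mortality_table", "make_utility_table",
    "load_life_table", "load_event_mortality_table", "load_utility_table",
    "default_fixtures",
]

_SEXES = ("male", "female")
MAX_AGE = 110


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability by (integer age, sex)."""

    entries: dict[tuple[int, str], float]

    def annual_death_prob(self, age: float, sex: str) -> float:
        a = min(int(age), MAX_AGE)
        return self.entries[(a, sex)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"age": a, "sex": s, "value": v} for (a, s), v in sorted(self.entries.items())]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EventMortalityTable:
    """28/30-day case fatality by (age-band lower bound, sex, event)."""

    entries: dict[tuple[int, str, str], float]

    def lookup(self, age: float, sex: str, event: str) -> float:
        bounds = sorted({b for (b, s, e) in self.entries if s == sex and e == event})
        if not bounds:
            raise KeyError(f"no entries for sex={sex!r}, event={event!r}")
        lo = bounds[0]
        for b in bounds:
            if age >= b:
                lo = b
        return self.entries[(lo, sex, event)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"age": a, "sex": s, "event": e, "value": v}
                for (a, s, e), v in sorted(self.entries.items())]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class UtilityTable:
    """General-population utility weight by (integer age, sex)."""

    entries: dict[tuple[int, str], float]

    def utility(self, age: float, sex: str) -> float:
        a = min(int(age), MAX_AGE)
        return self.entries[(a, sex)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"age": a, "sex": s, "value": v} for (a, s), v in sorted(self.entries.items())]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FixtureSet:
    life_table: LifeTable
    event_mortality: EventMortalityTable
    utility: UtilityTable


def make_life_table(
    a: float = 8.0e-5,
    b: float = 0.08,
    c: float = 5.0e-4,
    sex_gap: float = 0.65,
) -> LifeTable:
    """Gompertz–Makeham life table: hazard ``c + a*exp(b*age)``.

    ``sex_gap`` multiplies the female hazard (female mortality below male at
    matched age).  Defaults are tuned so a 65-year-old male has an annual
    death probability near 0.015 and roughly 92% five-year survival, the
    magnitude general-population tables show at that age.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("Gompertz-Makeham parameters must be non-negative")
    entries: dict[tuple[int, str], float] = {}
    clamped = False
    for age in range(MAX_AGE + 1):
        h = c + a * math.exp(b * age)
        for sex in _SEXES:
            hs = h * (sex_gap if sex == "female" else 1.0)
            q = 1.0 - math.exp(-hs)
            if q > 1.0:
                q, clamped = 1.0, True
            entries[(age, sex)] = q
    if clamped:  # pragma: no cover - defensive
        warnings.warn("life-table probabilities clamped at 1", stacklevel=2)
    return LifeTable(entries)


_DEFAULT_28D = {
    # band lower bound -> 28/30-day case fatality; the 60-69 band anchors the
    # published cohort-level magnitudes (ischemic 0.189, ICH 0.48)
    "ischemic_stroke": {0: 0.10, 60: 0.189, 70: 0.27, 80: 0.38},
    "ich": {0: 0.35, 60: 0.48, 70: 0.58, 80: 0.68},
}


def make_event_mortality_table(
    base_28d: dict[str, dict[int, float]] | None = None,
) -> EventMortalityTable:
    """Stand-in 28/30-day case-fatality table by age band, sex and event.

    The default bands place a 65-year-old at 0.189 for ischemic stroke and
    0.48 for ICH; both sexes share the same stand-in values.
    """
    base = _DEFAULT_28D if base_28d is None else base_28d
    entries: dict[tuple[int, str, str], float] = {}
    for event, bands in base.items():
        for lo, p in bands.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{event} band {lo}: probability {p} outside [0, 1]")
            for sex in _SEXES:
                entries[(lo, sex, event)] = p
    return EventMortalityTable(entries)


def make_utility_table(u65: float = 0.83, slope: float = 0.03) -> UtilityTable:
    """Linear-in-age stand-in utilities: ``u65 - slope*(age-65)/10``, clamped.

    ``slope`` is the utility decline per decade of age; defaults give 0.83 at
    65 and 0.80 at 75, the magnitude of published general-population norms.
    """
    if not 0.0 <= u65 <= 1.0:
        raise ValueError(f"u65 must be in [0, 1], got {u65}")
    entries: dict[tuple[int, str], float] = {}
    for age in range(MAX_AGE + 1):
        u = min(1.0, max(0.0, u65 - slope * (age - 65) / 10.0))
        for sex in _SEXES:
            entries[(age, sex)] = u
    return UtilityTable(entries)


# ---------------------------------------------------------------------------
# delimited-file loaders (drop-in replacements for the synthetic tables)
# ---------------------------------------------------------------------------

def _check_prob(df: pd.DataFrame, what: str) -> None:
    bad = df[(df["value"] < 0) | (df["value"] > 1)]
    if not bad.empty:
        raise ValueError(f"{what}: values outside [0, 1] at rows {bad.index.tolist()}")


def load_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    _check_prob(df, "life table")
    return LifeTable({(int(r.age), str(r.sex)): float(r.value) for r in df.itertuples()})


def load_event_mortality_table(path: str | Path) -> EventMortalityTable:
    df = pd.read_csv(path)
    _check_prob(df, "event mortality table")
    return EventMortalityTable(
        {(int(r.age), str(r.sex), str(r.event)): float(r.value) for r in df.itertuples()}
    )


def load_utility_table(path: str | Path) -> UtilityTable:
    df = pd.read_csv(path)
    _check_prob(df, "utility table")
    return UtilityTable({(int(r.age), str(r.sex)): float(r.value) for r in df.itertuples()})


def default_fixtures() -> FixtureSet:
    """The default synthetic fixture bundle used throughout the package."""
    return FixtureSet(
        life_table=make_life_table(),
        event_mortality=make_event_mortality_table(),
        utility=make_utility_table(),
    )
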