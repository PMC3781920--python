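"""Structured-text (YAML) configuration: parameters, profile, fixtures, runs.

The same dotted-path override dialect used by the sensitivity-analysis
scenarios drives configuration patches, so a run config can override any
parameter or profile field from the command line or a file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import fixtures as fx
from .owsa import apply_overrides
from .parameters import (
    CohortProfile,
    DistributionSpec,
    ParameterSet,
    build_default_parameters,
)

__all__ = ["ConfigError", "RunConfig", "load_run_config",
           "parameters_to_yaml", "parameters_from_yaml",
           "distributions_to_dict", "distributions_from_dict"]


class ConfigError(ValueError):
    """Configuration problem, carrying the offending field path."""

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


def parameters_to_yaml(ps: ParameterSet, path: str | Path) -> None:
    data = asdict(ps)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def parameters_from_yaml(path: str | Path) -> ParameterSet:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(str(path), "expected a mapping of parameter fields")
    if "chads2_stroke_table" in data:
        data["chads2_stroke_table"] = {
            int(k): float(v) for k, v in data["chads2_stroke_table"].items()
        }
    try:
        return ParameterSet(**data)
    except TypeError as exc:
        raise ConfigError(str(path), str(exc)) from exc


def distributions_to_dict(dists: dict[str, DistributionSpec]) -> dict:
    return {k: {"family": d.family, "params": list(d.params)}
            for k, d in dists.items()}


def distributions_from_dict(data: dict) -> dict[str, DistributionSpec]:
    out = {}
    for key, spec in data.items():
        try:
            out[key] = DistributionSpec(spec["family"], tuple(spec["params"]))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"distributions.{key}", str(exc)) from exc
    return out


@dataclass
class RunConfig:
    """Inputs for a command-line run.

    ``overrides`` uses the dotted dialect (``params.<field>`` /
    ``profile.<field>``); ``fixture_files`` maps any of
    life_table/event_mortality/utility to a CSV path (generated synthetic
    tables are used where omitted).
    """

    profile: CohortProfile = field(default_factory=CohortProfile)
    overrides: dict = field(default_factory=dict)
    fixture_files: dict = field(default_factory=dict)
    n_draws: int = 1000
    seed: int = 1234
    wtp_grid: list = field(default_factory=lambda: list(range(0, 205000, 5000)))

    def build(self):
        """Materialise (parameters, distributions, profile, fixtures)."""
        ps, dists = build_default_parameters()
        try:
            ps, profile = apply_overrides(self.overrides, ps, self.profile)
        except ValueError as exc:
            raise ConfigError("overrides", str(exc)) from exc

        loaders = {
            "life_table": fx.load_life_table,
            "event_mortality": fx.load_event_mortality_table,
            "utility": fx.load_utility_table,
        }
        bundle = fx.default_fixtures()
        parts = {"life_table": bundle.life_table,
                 "event_mortality": bundle.event_mortality,
                 "utility": bundle.utility}
        for key, path in self.fixture_files.items():
            if key not in loaders:
                raise ConfigError(f"fixture_files.{key}",
                                  f"unknown table, expected one of {sorted(loaders)}")
            if not Path(path).exists():
                raise ConfigError(f"fixture_files.{key}", f"file not found: {path}")
            parts[key] = loaders[key](path)
        fixtures = fx.FixtureSet(**parts)
        return ps, dists, profile, fixtures


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(str(path), "expected a mapping")
    known = {"profile", "overrides", "fixture_files", "n_draws", "seed", "wtp_grid"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], f"unknown config key; valid: {sorted(known)}")
    prof_data = data.get("profile", {})
    try:
        profile = CohortProfile(**prof_data)
    except (TypeError, ValueError) as exc:
        raise ConfigError("profile", str(exc)) from exc
    try:
        n_draws = int(data.get("n_draws", 1000))
        seed = int(data.get("seed", 1234))
    except (TypeError, ValueError) as exc:
        raise ConfigError("n_draws/seed", str(exc)) from exc
    return RunConfig(
        profile=profile,
        overrides=dict(data.get("overrides", {})),
        fixture_files=dict(data.get("fixture_files", {})),
        n_draws=n_draws,
        seed=seed,
        wtp_grid=list(data.get("wtp_grid", range(0, 205000, 5000))),
    )
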