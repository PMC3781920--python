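"""Shared fixtures: default model inputs and degenerate (zero-risk) variants."""

import warnings

import pytest

from afcea.fixtures import (
    FixtureSet,
    default_fixtures,
    make_event_mortality_table,
    make_life_table,
    make_utility_table,
)
from afcea.parameters import CohortProfile, build_default_parameters


@pytest.fixture(scope="session")
def default_inputs():
    """(ParameterSet, distribution map) for the basecase."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # text-vs-table cost provenance notices
        return build_default_parameters()


@pytest.fixture(scope="session")
def params(default_inputs):
    return default_inputs[0]


@pytest.fixture(scope="session")
def dists(default_inputs):
    return default_inputs[1]


@pytest.fixture(scope="session")
def profile():
    return CohortProfile()


@pytest.fixture(scope="session")
def fixtures_bundle():
    return default_fixtures()


@pytest.fixture(scope="session")
def immortal_fixtures():
    """Fixture bundle with zero mortality everywhere (flat utilities kept)."""
    return FixtureSet(
        life_table=make_life_table(0.0, 0.08, 0.0, 1.0),
        event_mortality=make_event_mortality_table(
            {"ischemic_stroke": {0: 0.0}, "ich": {0: 0.0}}),
        utility=make_utility_table(0.83, 0.0),
    )


@pytest.fixture(scope="session")
def no_event_params(params):
    """Parameters with every stochastic clinical event switched off."""
    return params.replace(
        chads2_stroke_table={k: 0.0 for k in range(7)},
        p_bleed_no_warfarin=0.0,
        p_pulm_tox_annual=0.0,
        p_complication_stroke=0.0,
        p_complication_tia=0.0,
        p_complication_tamponade=0.0,
        p_complication_pv_stenosis=0.0,
        p_recur_ablation=0.0,
        p_recur_aad=0.0,
    )
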