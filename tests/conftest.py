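"""Shared fixtures: small fast cohorts plus one session-scoped full run."""

import pytest

from evband.cohort import generate_cohort
from evband.config import default_config, default_demographics
from evband.costs_report import run_pipeline
from evband.regimens import VialFormulary


@pytest.fixture(scope="session")
def formulary() -> VialFormulary:
    return VialFormulary(vials=((20.0, 698.0), (30.0, 1047.0)))


@pytest.fixture(scope="session")
def default_pk():
    return default_config().pk


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 80-subject cohort from the default demographics."""
    return generate_cohort(default_demographics(n=80, seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """One full default pipeline run (n=500, default seed), reused across tests."""
    return run_pipeline(default_config())
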