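"""Shared fixtures: model inputs, small configs, and the reference run."""

import numpy as np
import pytest

from drysim import economics, energy_feed as ef, ghg, lactation as lac
from drysim.config import ScenarioConfig


@pytest.fixture(scope="session")
def curve_table():
    return lac.load_curve_table()


@pytest.fixture(scope="session")
def prices():
    return economics.load_prices()


@pytest.fixture(scope="session")
def factors():
    return ghg.load_emission_factors()


@pytest.fixture(scope="session")
def rations():
    return ef.load_rations()


@pytest.fixture(scope="session")
def constants():
    return ef.EnergyConstants()


@pytest.fixture
def rng():
    return np.random.default_rng(20170101)


@pytest.fixture(scope="session")
def small_cfg():
    """A cheap configuration for structural and smoke tests."""
    return ScenarioConfig(n_herds=3, n_places=30, warmup_years=2,
                          scenario_years=2, seed=11)


@pytest.fixture(scope="session")
def reference():
    """The full-scale reference experiment (expensive; shared by the
    acceptance tests)."""
    from drysim import experiments
    return experiments.run_reference(ScenarioConfig())
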