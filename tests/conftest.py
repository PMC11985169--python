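"""Shared fixtures: one synthetic study system reused across the suite."""

import numpy as np
import pandas as pd
import pytest

import entrange as er
from entrange.maxent import MaxentModel


@pytest.fixture(scope="session")
def scenario():
    return er.SyntheticScenario(grid_rows=60, grid_cols=60, n_presences=200,
                                seed=11)


@pytest.fixture(scope="session")
def stack(scenario):
    return er.generate_stack(scenario)


@pytest.fixture(scope="session")
def suitability(scenario, stack):
    return er.true_suitability(stack, scenario.true_coefficients,
                               intercept=scenario.intercept)


@pytest.fixture(scope="session")
def occurrences(scenario, suitability):
    return er.sample_presences(suitability, scenario.geometry,
                               scenario.n_presences, seed=12)


@pytest.fixture(scope="session")
def model(stack, occurrences):
    return MaxentModel.from_stack(stack, occurrences, fc="LQ", rm=1.0,
                                  n_knots=8, background_size=2000, seed=13)


@pytest.fixture(scope="session")
def results(model):
    return model.fit()


@pytest.fixture(scope="session")
def signal_tables(model):
    """(presences, background) variable tables with a strong known signal."""
    return model.presences, model.background


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
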