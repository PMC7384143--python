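import dataclasses

import numpy as np
import pandas as pd
import pytest

from leafprod.synthetic import SyntheticScenario, generate_region


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A quick 300-cell scenario used by most integration tests."""
    return SyntheticScenario(nx=20, ny=15, n_species=200, seed=42)


@pytest.fixture(scope="session")
def region(small_scenario):
    """One fully simulated region (climate, ranges, traits, productivity)."""
    return generate_region(small_scenario)


@pytest.fixture(scope="session")
def default_region():
    """The default 1200-cell study scenario, simulated once per session."""
    return generate_region(SyntheticScenario())


@pytest.fixture()
def rng():
    return np.random.default_rng(20200406)
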