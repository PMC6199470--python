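import numpy as np
import pytest

from legacylag import pipeline
from legacylag.climatology import default_window_schedule
from legacylag.synthetic import (VariableSpec, ClimateGenConfig,
                                 default_climate_config,
                                 generate_climate_grid, generate_sites)


@pytest.fixture(scope="session")
def schedule():
    return default_window_schedule(collection_year=2011)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study realisation, shared read-only by tests:
    60 sites x 3 plots, monthly climate 1950-2011, 5 signal taxa driven
    by the 1960-1969 window plus 25 background taxa, depth 3000."""
    return pipeline.simulate_study(seed=11)


@pytest.fixture(scope="session")
def small_grid():
    """A small noise-free grid with known structure for exact checks."""
    variables = {
        "tmp": VariableSpec(base=2.0, trend="linear", slope=0.05,
                            seasonal_amplitude=8.0, lat_gradient=-0.5),
        "pre": VariableSpec(base=50.0, trend="none", seasonal_amplitude=20.0,
                            lon_gradient=2.0),
    }
    config = ClimateGenConfig(lat_min=30.0, lat_max=32.0, lon_min=85.0,
                              lon_max=87.0, start_year=1950, end_year=2011,
                              variables=variables, seed=0)
    return generate_climate_grid(config)


@pytest.fixture(scope="session")
def small_designs(small_grid):
    return generate_sites(small_grid, n_sites=6, plots_per_site=2, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
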