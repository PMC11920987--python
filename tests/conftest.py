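import numpy as np
import pytest

from sagloc.model import ModelParams
from sagloc.peripheral import erb_band_centers
from sagloc.schemes import flat_scheme
from sagloc.synthetic import (SyntheticListenerSpec, make_dtf_set,
                              simulate_responses)


@pytest.fixture(scope="session")
def grid():
    return erb_band_centers()


@pytest.fixture(scope="session")
def listener(grid):
    """One deterministic synthetic listener (templates + raw DTFs)."""
    return make_dtf_set(SyntheticListenerSpec(rng_seed=3), grid=grid)


@pytest.fixture(scope="session")
def templates(listener):
    return listener[0]


@pytest.fixture(scope="session")
def true_params():
    return ModelParams(gamma=6.0, s=0.7, epsilon=12.79)


@pytest.fixture(scope="session")
def recovery_responses(templates, grid, true_params):
    """~1000 median-plane responses simulated under the Flat scheme."""
    return simulate_responses(templates, flat_scheme(grid), true_params,
                              n_per_target=14, seed=7)
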