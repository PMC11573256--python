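import numpy as np
import pytest

from icresponse.cohort import default_group_effects, generate_cohort
from icresponse.stimuli import build_noise_train, build_tone_grid, speech_catalog


@pytest.fixture(scope="session")
def grid():
    return build_tone_grid(1000.0, 32000.0, 0.0625, 0.0, 75.0, 5.0)


@pytest.fixture(scope="session")
def catalog():
    return speech_catalog()


@pytest.fixture(scope="session")
def train():
    return build_noise_train(10.0, 6, 25.0)


@pytest.fixture(scope="session")
def small_cohort(grid, catalog, train):
    """A small but complete four-group cohort (6 sites per group)."""
    effects = default_group_effects(n_sites=6)
    return generate_cohort(effects, grid=grid, speech=catalog, train=train, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
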