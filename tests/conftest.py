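import numpy as np
import pytest

from mentalpong.synth import generate_dataset, make_grid
from mentalpong.task import sample_conditions


@pytest.fixture(scope="session")
def conditions20():
    return sample_conditions(20, seed=3)


@pytest.fixture(scope="session")
def grid20(conditions20):
    return make_grid(conditions20)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic session kept small for unit tests."""
    return generate_dataset(n_conditions=30, n_units=80, n_trials=6,
                            missing_frac=0.02, seed=21)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default-scale synthetic session (79 conditions, 200 units)."""
    return generate_dataset(seed=1)
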