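import numpy as np
import pytest

from romagree.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study_table():
    """One full synthetic study table shared across pipeline tests."""
    return simulate_study(n_participants=35, seed=11)


@pytest.fixture
def clean_cfg():
    """Noise-free pure two-way config: no bias, no rounding, no interaction."""
    return SimulationConfig(
        mu=100.0,
        sigma_b=10.0,
        sigma_e=2.5,
        n_subjects=70,
        device_bias={"POM": 0.0},
        rounding={"POM": None},
        seed=5,
    )
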