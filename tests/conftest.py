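import numpy as np
import pytest

from leafwp import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated campaign: 229 labeled spectra with noise."""
    return generate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free fixture: the Psi -> spectrum map is injective."""
    return generate_dataset(
        SimulationConfig(seed=0, noise_sd_additive=0.0, noise_sd_multiplicative=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
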