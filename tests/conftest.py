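import numpy as np
import pytest

from mpalesion.synthetic_data import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """Desk-scale phantom geometry used across the suite."""
    return PhantomConfig(
        height=32, width=32, n_wavelengths=32, lesion_radius_range=(4.0, 9.0), seed=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_phantom_config):
    return generate_dataset(8, small_phantom_config, 0.5, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
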