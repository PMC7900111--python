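import numpy as np
import pytest

from ildseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-size phantom (48x48x16, 4 sequences)."""
    return generate_phantom(PhantomConfig(seed=7))


def small_config(**kwargs) -> PhantomConfig:
    """A fast 32x32x8 phantom config for unit tests."""
    base = dict(
        grid_shape=(32, 32, 8),
        lesion_count_range=(1, 2),
        lesion_radius_range=(2.0, 4.0),
        vessel_count=1,
        seed=0,
    )
    base.update(kwargs)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_config(seed=3))


@pytest.fixture(scope="session")
def noise_free_single_lesion():
    """Noise-free, vessel-free, one-lesion phantom: construction is exact."""
    return generate_phantom(
        small_config(seed=5, noise_sd=0.0, vessel_count=0, lesion_count_range=(1, 1))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
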