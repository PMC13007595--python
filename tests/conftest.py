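import numpy as np
import pytest

from dynrad.phantom import (
    PhantomParams,
    generate_phantom,
    make_noise_instances,
    rescale_to_unit,
)


@pytest.fixture(scope="session")
def small_params():
    """A fast 12-frame phantom used across the suite."""
    return PhantomParams(grid_size=64, n_frames=12, r_endo_ed=10.0, r_epi_ed=16.0,
                         texture_seed=7)


@pytest.fixture(scope="session")
def small_sequence(small_params):
    return rescale_to_unit(generate_phantom(small_params))


@pytest.fixture(scope="session")
def default_sequence():
    """The default 128x128, 25-frame phantom, rescaled to [0, 1]."""
    return rescale_to_unit(generate_phantom(PhantomParams()))


@pytest.fixture(scope="session")
def small_instances(small_sequence):
    """Reference + 2 levels x 2 replicates of the small phantom."""
    return make_noise_instances(small_sequence, [0.01, 0.03], replicates=2, base_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
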