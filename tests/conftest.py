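import numpy as np
import pytest

from morphoscreen import PopulationSpec, make_two_class_table


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size generative spec for fast unit tests."""
    shift = np.zeros(4)
    shift[:2] = 0.6
    return PopulationSpec(
        n_features=60,
        n_latents=4,
        class_shift=shift,
        informative_features=(0, 1, 2, 3),
        direct_offset=1.5,
        noise_sd=0.45,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_table(small_spec):
    return make_two_class_table(small_spec, 60, 60)


@pytest.fixture(scope="session")
def default_spec():
    """Full-size study conditions: 302 features, default separation."""
    return PopulationSpec(seed=1)


@pytest.fixture(scope="session")
def default_table(default_spec):
    """101 naive + 96 model objects, the documented training regime."""
    return make_two_class_table(default_spec, 101, 96)
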