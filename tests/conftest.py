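import numpy as np
import pytest

from spikebright.encoding import AfferentPopulation, ReceptiveField, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """A 10x10 grid of DoG fields over a 20x20 image (fast to evaluate)."""
    return build_grid(20, 2, seed=7)


@pytest.fixture
def single_field_population():
    """One hand-specified field in a small image, for closed-form checks."""
    field = ReceptiveField(center=(2.0, 2.0), sigma_c=1.0, sigma_s=2.0, ratio=0.25)
    return AfferentPopulation([field], image_size=6, spacing=6)
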