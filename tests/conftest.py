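import numpy as np
import pytest

from finseg.synthetic import SyntheticSpec, generate_dataset, generate_sample


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale generator settings: 160-px frames, 2-5 px defect radii."""
    return SyntheticSpec(image_size=160, defect_radius_range=(2.0, 5.0))


@pytest.fixture(scope="session")
def sample_160(small_spec):
    return generate_sample(small_spec, seed=7)


@pytest.fixture(scope="session")
def dataset_160(small_spec):
    return generate_dataset(12, small_spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
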