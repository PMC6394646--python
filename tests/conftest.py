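import numpy as np
import pytest

from adlfuse.frame import DEFAULT_FRAME, Frame


@pytest.fixture
def frame15() -> Frame:
    return DEFAULT_FRAME


@pytest.fixture
def frame4() -> Frame:
    return Frame(("a", "b", "c", "d"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic bundle shared across tests (8 images/class)."""
    from adlfuse.simulate import SimConfig, generate_dataset

    return generate_dataset(SimConfig(seed=42, samples_per_class=8, images_per_bout=4))
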