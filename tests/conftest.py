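import numpy as np
import pytest

from ospreycaps.capsnet import CapsNetArchitecture
from ospreycaps.imaging import SyntheticSmearConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def smear_images():
    """Small balanced synthetic smear set (20 per class)."""
    return generate_synthetic_dataset(SyntheticSmearConfig(seed=7), 20)


@pytest.fixture(scope="session")
def arch():
    return CapsNetArchitecture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
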