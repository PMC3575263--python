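import numpy as np
import pytest

from slidesplit.fixtures import generate_slide


@pytest.fixture(scope="session")
def brightfield_slide():
    """Default brightfield fixture: 2048x1536, 8 textured blobs on white."""
    return generate_slide(mode="brightfield")


@pytest.fixture(scope="session")
def fluorescent_slide():
    """Default fluorescent fixture: 2048x1536, 8 bright blobs on black."""
    return generate_slide(mode="fluorescent")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
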