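import numpy as np
import pytest

from mbdwi import BValueScheme


@pytest.fixture
def scheme() -> BValueScheme:
    """The default 12-b-value protocol (b = 0…1500 s/mm², per-b NEX)."""
    return BValueScheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240612)
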