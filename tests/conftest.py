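import numpy as np
import pytest

from fibrilphase.electrolyte import SolutionConditions
from fibrilphase.geometry import FibrilGeometry


@pytest.fixture(scope="session")
def lysozyme():
    """Lysozyme fibril geometry used in the worked examples."""
    return FibrilGeometry.from_aspect_ratio(D=20.9 / 5.4, aspect_ratio=95.0)


@pytest.fixture(scope="session")
def cond_ph2():
    return SolutionConditions(pH=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
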