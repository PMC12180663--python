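import numpy as np
import pytest

from dotphantom.absorbers import (ConcentrationPair, default_extinction_system)
from dotphantom.synthetic import SyntheticScene


@pytest.fixture(scope="session")
def system():
    return default_extinction_system()


@pytest.fixture(scope="session")
def noise_free_scene(system):
    """Concentration-defined synthetic scene without camera noise."""
    return SyntheticScene(conc=ConcentrationPair(0.02, 0.03), system=system,
                          peak_counts=None, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
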