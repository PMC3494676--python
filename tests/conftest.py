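import numpy as np
import pytest

from admixpurge.genome import GeneticMap
from admixpurge.markers import make_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """A short chromosome with few loci: fast to simulate, fully featured."""
    return GeneticMap(length_morgans=2.0, n_loci=50, n_markers=5)


@pytest.fixture
def diagnostic_panel():
    return make_panel("diagnostic", 5)
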