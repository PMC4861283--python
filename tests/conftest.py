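import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oleofinder.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down study: fast enough for unit tests, same structure."""
    return SimulationConfig(
        seed=7, n_ogs=400, n_genes_expr=400, n_genes_de=300, n_de_genes=30,
        n_promoters=10, n_families=3,
    )
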