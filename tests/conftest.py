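import warnings

import numpy as np
import pytest

from m6adosage.synth import SynthConfig, simulate

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene dataset shared by cheap structural tests."""
    return simulate(SynthConfig(genes_per_chromosome=10, seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """Full 2,000-gene dataset at generator defaults (the study conditions)."""
    return simulate(SynthConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
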