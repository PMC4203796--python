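import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from crossdev.synthetic import GenerationConfig, generate_truth, simulate_counts

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_truth():
    """40 triads, 20% divergent in the first species, deterministic."""
    config = GenerationConfig(n_genes=40, fraction_divergent=0.2)
    return generate_truth(config, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_counts(small_truth, depth=1e6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
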