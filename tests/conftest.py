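import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from pol2poise.config import PipelineConfig
from pol2poise.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene simulated state shared across tests (seed-fixed)."""
    return simulate_dataset(SimulationConfig(n_genes=300, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
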