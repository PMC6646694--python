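import numpy as np
import pytest

from fconn import (SimulationConfig, default_partition,
                   default_planted_component, generate_study,
                   load_significant_edges)


@pytest.fixture(scope="session")
def partition():
    return default_partition()


@pytest.fixture(scope="session")
def published_edges():
    return load_significant_edges()


@pytest.fixture(scope="session")
def small_study():
    """A fast planted-effect study reused across tests (10 vs 8 subjects,
    sign-flipped 30-edge sensory-motor/auditory component)."""
    config = SimulationConfig(n_patients=10, n_controls=8, n_frames=120,
                              planted_edges=default_planted_component(),
                              seed=7)
    return generate_study(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
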