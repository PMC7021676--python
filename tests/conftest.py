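import numpy as np
import pytest

from squeaktrace import ArenaConfig, BehaviorParams, simulate_dyad


@pytest.fixture(scope="session")
def short_recording():
    """A 5-minute dyad with frequent emissions, shared across tests."""
    arena = ArenaConfig(duration=300.0)
    behavior = BehaviorParams(emission_hazard_near=0.01, emission_hazard_far=5e-4)
    tracks, truth = simulate_dyad(arena, behavior, seed=11)
    return arena, behavior, tracks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
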