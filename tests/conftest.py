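import numpy as np
import pytest

from baldwinsim.config import (
    EvolutionConfig,
    GridConfig,
    LearningConfig,
    SeasonConfig,
    SimulationConfig,
    VitalConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small, fast simulation configuration for engine-level tests."""
    return SimulationConfig(
        grid=GridConfig(m=10, n_food_cells=40, phi_max=2),
        seasons=SeasonConfig(length=50, pi0=(1.0, 0.0)),
        vital=VitalConfig(c_r=200.0, c_d=2000.0, delta_s=0.25),
        learning=LearningConfig(),
        evolution=EvolutionConfig(n_founders=20, founder_energy=20.0),
        agent_type="learn_actions_skill",
        L=200,
        log_every=10,
    ).validate()
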