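import numpy as np
import pytest

from msdwell import PotentialParams, SimulationConfig, Trajectory


@pytest.fixture
def symmetric_params():
    return PotentialParams(alpha=1.0, beta=0.0)


@pytest.fixture
def tilted_params():
    return PotentialParams(alpha=1.0, beta=0.08)


def make_trajectory(states, dt=1.0, params=PotentialParams(1.0, 0.0), epsilon=0.13):
    """Build a Trajectory around a hand-written state path (for labelling tests)."""
    states = np.asarray(states, dtype=float)
    config = SimulationConfig(
        params=params, epsilon=epsilon, n_steps=max(states.size - 1, 1), dt=dt
    )
    return Trajectory(times=np.arange(states.size) * dt, states=states, config=config)
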