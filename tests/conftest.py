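import numpy as np
import pytest

from wormlawn import SimulationConfig, analyze_animal, simulate_trajectory


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated animal (40 min, 3 Hz)."""
    return simulate_trajectory(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def analyzed_default(sim_default):
    traj, lawn, truth = sim_default
    return analyze_animal(traj, lawn, ground_truth=truth)


@pytest.fixture(scope="session")
def short_sim():
    """A short, fully visible animal for fast frame-level tests."""
    cfg = SimulationConfig(seed=11, duration_s=300.0, missing_frac=0.0)
    return simulate_trajectory(cfg)


def circle_distance(points: np.ndarray, radius: float) -> np.ndarray:
    """Independent signed distance to a circular lawn centered at the origin."""
    return radius - np.linalg.norm(np.atleast_2d(points), axis=1)
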