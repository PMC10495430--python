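import warnings

import numpy as np
import pytest

from flywide.synthetic import (
    BehaviorSimConfig,
    NeuralSimConfig,
    generate_activity,
    generate_behavior,
    generate_cells,
)

# short-session configs intentionally trip the duration warning; silence it
warnings.filterwarnings(
    "ignore", message="duration is shorter than 10x the slow tendency timescale"
)


@pytest.fixture(scope="session")
def behavior_short():
    """5-minute behavioral simulation at 10 Hz (default state structure)."""
    return generate_behavior(BehaviorSimConfig(duration=300.0, seed=1))


@pytest.fixture(scope="session")
def behavior_10min():
    return generate_behavior(BehaviorSimConfig(duration=600.0, seed=2))


@pytest.fixture(scope="session")
def small_dataset(behavior_short):
    """60-cell population with clusters, motion cells and noise, on the
    5-minute behavior session."""
    cfg = NeuralSimConfig(
        n_cells=60, n_residual_clusters=4, seed=1, tau_slow_range=(10.0, 25.0)
    )
    cells = generate_cells(cfg)
    activity = generate_activity(behavior_short, cells, cfg)
    return cfg, cells[0], activity


@pytest.fixture(scope="session")
def noiseless_dataset(behavior_short):
    """Small noiseless, cluster-free population: activity is exactly the
    behavior-kernel prediction."""
    cfg = NeuralSimConfig(
        n_cells=5, n_residual_clusters=0, noise_sd=0.0, cell_dynamics_sd=0.0,
        n_motion_cells=0, seed=2, tau_slow_range=(10.0, 20.0),
    )
    cells = generate_cells(cfg)
    activity = generate_activity(behavior_short, cells, cfg)
    return cfg, cells[0], activity


@pytest.fixture(scope="session")
def coarse_grids():
    """Kernel search grids sized for 5-10 minute test sessions."""
    return np.geomspace(0.3, 30.0, 8), np.linspace(-10.0, 25.0, 8)


@pytest.fixture(scope="session")
def behavior_long():
    """Full-length (20-minute) behavioral session at the default structure."""
    return generate_behavior(BehaviorSimConfig(duration=1200.0, seed=1))
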