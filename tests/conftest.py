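import numpy as np
import pytest

from bretropy.simulate import (
    ConditionKinetics,
    NoiseSpec,
    SimulationConfig,
    simulate_experiment_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_experiment_set():
    """Two noisy conditions, 2 experiments x 2 wells, short protocol."""
    cfg = SimulationConfig(
        conditions=(
            ConditionKinetics("ctrl", 1.0, 0.0, 0.004, NoiseSpec("gaussian_iid", 0.005)),
            ConditionKinetics("drug", 1.0, 0.05, 0.005, NoiseSpec("gaussian_iid", 0.003)),
        ),
        n_experiments=2,
        n_wells=2,
        dt=30.0,
        baseline_duration=300.0,
        total_duration=1200.0,
        seed=7,
    )
    return simulate_experiment_set(cfg)
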