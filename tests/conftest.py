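import numpy as np
import pytest

from hrssm import (
    DielSchedule,
    MCMCConfig,
    OUParams,
    ReceiverArray,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def grid_array() -> ReceiverArray:
    return ReceiverArray.grid(5, 300.0)


@pytest.fixture(scope="session")
def quick_mcmc() -> MCMCConfig:
    """Short chains for structural tests (not for coverage claims)."""
    return MCMCConfig(n_chains=3, n_burnin=600, n_samples=600, thin=3, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """One fast-exploring fish, one day, 30-min pooling: 28 steps.

    Small enough for repeated fitting in unit tests, informative enough that
    the center and epsilon are identified.
    """
    cfg = SimulationConfig.canonical(3, step_minutes=30, days=1)
    traj, calib, tensor, data = simulate_dataset(cfg, seed=2024)
    return cfg, traj, calib, data


@pytest.fixture(scope="session")
def small_fit(small_dataset, quick_mcmc):
    from hrssm import fit_ssm

    cfg, traj, calib, data = small_dataset
    return cfg, traj, fit_ssm(data, cfg.array, calib, config=quick_mcmc)
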