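import numpy as np
import pytest

from sleepnet import (BinarySymptomTable, EstimationConfig, GraphSpec,
                      IsingModel, plant_model, sample_ising)


@pytest.fixture(scope="session")
def fast_config() -> EstimationConfig:
    """Estimation settings for simulation-heavy tests: a shorter λ grid and a
    looser (still conservative) convergence tolerance."""
    return EstimationConfig(lambda_count=25, convergence_tolerance=1e-5)


@pytest.fixture(scope="session")
def planted_p10() -> IsingModel:
    """A 10-node sparse model with exactly calibrated 0.3 prevalences."""
    return plant_model(GraphSpec(density=0.25), [0.3] * 10, seed=1)


@pytest.fixture(scope="session")
def independent_p10() -> IsingModel:
    """Ten independent nodes at prevalence 0.3 (empty network)."""
    return plant_model(GraphSpec(density=0.0), [0.3] * 10, seed=1)


@pytest.fixture(scope="session")
def sample_p10(planted_p10) -> BinarySymptomTable:
    return sample_ising(planted_p10, 1500, seed=7, method="exact")


def random_model(p: int, rng: np.random.Generator, density: float = 0.4,
                 max_abs: float = 1.0) -> IsingModel:
    """Ad-hoc random Ising model for property tests (no calibration)."""
    tau = rng.uniform(-1.0, 1.0, p)
    omega = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                omega[i, j] = omega[j, i] = rng.uniform(-max_abs, max_abs)
    return IsingModel(tau, omega)
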