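import numpy as np
import pandas as pd
import pytest

from chumrun.synthetic import SimulationConfig, simulate_cohort_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    return simulate_cohort_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noiseless dataset with exhaustive age surveys (exact recovery case)."""
    cfg = SimulationConfig(seed=5, noise_sd=0.0, exhaustive_surveys=True)
    return simulate_cohort_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_regression_data(rng, n=22, s=4):
    """Small covariate panel + response for oracle comparisons."""
    Z = pd.DataFrame(
        rng.standard_normal((n, s)),
        columns=[f"z{i+1}" for i in range(s)],
    )
    beta = np.zeros(s)
    beta[0] = 0.8
    if s > 1:
        beta[1] = -0.5
    y = 1.0 + Z.to_numpy() @ beta + rng.standard_normal(n) * 0.4
    return y, Z
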