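import numpy as np
import pandas as pd
import pytest

from methylsurv.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim5000():
    """Default-configuration cohort at n=5000 (calibration-scale)."""
    return simulate_cohort(SimulationConfig(n_subjects=5000, seed=1))


@pytest.fixture(scope="session")
def sim1000():
    return simulate_cohort(SimulationConfig(n_subjects=1000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_betas():
    """Four subjects, all ten score CpGs, simple values."""
    from methylsurv.scores import MRSCORE_WEIGHTS

    cpgs = list(MRSCORE_WEIGHTS)
    data = np.linspace(0.1, 0.9, 10)[:, None] * np.array([0.5, 0.8, 1.0, 1.2])[None, :]
    data = np.clip(data, 0.01, 0.99)
    return pd.DataFrame(data, index=cpgs, columns=[f"P{i}" for i in range(4)])
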