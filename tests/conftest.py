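import numpy as np
import pytest

import rsmeta as rs
from rsmeta.types import ArmRecord, StudyDataset


@pytest.fixture
def toy_ds() -> StudyDataset:
    """Two studies x two arms, m=3, all fields observed."""
    arms = [
        ArmRecord("s1", "a1", 100, 8.1, (0, 0, 0), se=0.15),
        ArmRecord("s1", "a2", 120, 7.6, (1, 1, 0), se=0.12),
        ArmRecord("s2", "a1", 80, 8.4, (0, 0, 0), se=0.20),
        ArmRecord("s2", "a2", 90, 7.9, (0, 1, 1), se=0.18),
    ]
    return StudyDataset(arms, ["A", "B", "C"])


@pytest.fixture(scope="session")
def sim_small():
    """A small review-like synthetic dataset with missingness and clusters."""
    cfg = rs.SimConfig(
        n_studies=60,
        m=4,
        beta=(-0.4, -0.2, 0.0, 0.1),
        tau=0.15,
        component_prevalence=(0.55, 0.4, 0.3, 0.25),
        seed=101,
    )
    ds, truth = rs.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def base_draws_small(sim_small):
    """A short but converged base-model fit of the small dataset."""
    _, ds, _ = sim_small
    config = rs.ModelConfig(chains=2, burnin=800, iterations=2000, seed=7)
    return rs.fit_base_model(ds, config)


def mcse_median(chain_draws: np.ndarray, n_batches: int = 40) -> float:
    """Batch-means Monte Carlo SE of the posterior median estimator."""
    x = np.asarray(chain_draws).reshape(-1)
    bs = len(x) // n_batches
    meds = [np.median(x[i * bs:(i + 1) * bs]) for i in range(n_batches)]
    return float(np.std(meds, ddof=1) / np.sqrt(n_batches))


def mcse_mean(chain_draws: np.ndarray, n_batches: int = 40) -> float:
    """Batch-means Monte Carlo SE of the posterior mean estimator."""
    x = np.asarray(chain_draws).reshape(-1)
    bs = len(x) // n_batches
    means = [np.mean(x[i * bs:(i + 1) * bs]) for i in range(n_batches)]
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))
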