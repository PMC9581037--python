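import numpy as np
import pytest

from smlm_bayescluster import GroundTruthConfig, make_table, simulate_ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def small_table(rng):
    """60 localizations: two tight blobs plus sparse background."""
    a = rng.normal([500.0, 500.0], 20.0, size=(25, 2))
    b = rng.normal([1500.0, 1400.0], 20.0, size=(25, 2))
    bg = rng.uniform(0.0, 2000.0, size=(10, 2))
    xy = np.vstack([a, b, bg])
    sd = rng.gamma(5.0, 1.0 / 0.166667, size=len(xy))
    return make_table(xy[:, 0], xy[:, 1], sd)


@pytest.fixture(scope="session")
def benchmark_table():
    """One realization of the standard ten-cluster benchmark recipe."""
    return simulate_ground_truth(GroundTruthConfig(seed=12345))
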