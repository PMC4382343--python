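import numpy as np
import pytest

import spikemid as sm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lnb_dataset():
    """Moderate-size logistic-Bernoulli dataset with a 45-degree filter."""
    return sm.simulate.sigmoid_bernoulli_2d(4000, seed=7)


@pytest.fixture(scope="session")
def lnc_dataset():
    """Variance-coded 0/1/2-count dataset (mean count stimulus-independent)."""
    return sm.simulate.count_toys("variance-coded", 4000, seed=3)


@pytest.fixture(scope="session")
def worked_example():
    """Deterministic two-sequence experiment (A -> 3 spikes, B -> 1 spike)."""
    return sm.simulate.two_stimulus_worked_example()


def random_count_dataset(seed, family=None):
    """A small random dataset in one of the three spiking regimes."""
    rng = np.random.default_rng(seed)
    family = family or ("lnp", "lnb", "lnc")[seed % 3]
    N = int(rng.integers(200, 600))
    x = rng.standard_normal(N)
    if family == "lnp":
        counts = rng.poisson(np.exp(0.4 * x))
    elif family == "lnb":
        counts = (rng.uniform(size=N) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
    else:
        probs = np.stack([
            0.2 + 0.3 / (1 + np.exp(-x)),
            0.5 - 0.2 / (1 + np.exp(-x)),
            0.3 - 0.1 / (1 + np.exp(-x)),
        ])
        probs /= probs.sum(axis=0)
        u = rng.uniform(size=N)
        counts = (u[None, :] > np.cumsum(probs, axis=0)).sum(axis=0)
    return x, counts, family
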