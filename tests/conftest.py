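import numpy as np
import pytest

import radsurv as rs


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with real signal, shared across tests."""
    cfg = rs.SimConfig(n_cases=150, n_features=24, block_size=6, seed=11)
    features, cohort, aug = rs.generate_cohort(cfg)
    return features, cohort, aug


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose survival carries no feature signal."""
    cfg = rs.SimConfig(n_cases=150, n_features=24, block_size=6, true_effects=(), seed=42)
    features, cohort, aug = rs.generate_cohort(cfg)
    return features, cohort, aug


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_survival(rng, n, censor_scale=2.0, risk=None):
    """Exponential survival with exponential censoring for ad-hoc tests."""
    lp = np.zeros(n) if risk is None else risk
    t = rng.exponential(1.0 / np.exp(lp))
    c = rng.exponential(censor_scale, n)
    return np.minimum(t, c), (t <= c).astype(int)
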