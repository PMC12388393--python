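import numpy as np
import pandas as pd
import pytest

from bloomnet.simulate import SimConfig, simulate_community


@pytest.fixture(scope="session")
def default_sim():
    """One default-design survey shared across tests (45 samples)."""
    return simulate_community(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A 15-sample survey (2 BR + 3 NR sites) for correlation-level checks."""
    return simulate_community(SimConfig(seed=11, n_sites_br=2, n_sites_nr=3))


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count table (3 samples x 4 ASVs)."""
    return pd.DataFrame(
        [[10, 0, 5, 5], [2, 8, 0, 10], [4, 4, 4, 4]],
        index=["s1", "s2", "s3"], columns=["a1", "a2", "a3", "a4"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
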