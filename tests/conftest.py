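import numpy as np
import pytest
from hypothesis import settings

import nichemod as nm

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_community():
    """A small trait-structured community with one active trait."""
    cfg = nm.SyntheticConfig(n=80, m=10, k_continuous=1, k_binary=1,
                             beta_opt=(1.0, 0.0), seed=42)
    return nm.simulate_community(cfg)


@pytest.fixture(scope="session")
def small_fit(small_community):
    """A short spike-and-slab fit on the small community."""
    occ, env, tr, truth = small_community
    x = env.values[:, 0]
    inits = nm.initial_values(occ, x, tr)
    opts = nm.McmcOptions(n_iter=600, n_chains=2, seed=7)
    return nm.fit(occ, x, tr, opts, inits)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240516)
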