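import numpy as np
import pytest

from soilchannels import mixing, synthgen


@pytest.fixture(scope="session")
def default_config():
    return synthgen.scenario("default", seed=42)


@pytest.fixture(scope="session")
def library(default_config):
    return synthgen.gen_sources(default_config)


@pytest.fixture(scope="session")
def consumers(default_config, library):
    return synthgen.gen_consumers(default_config, library)


@pytest.fixture(scope="session")
def small_posterior(default_config, library, consumers):
    """Short-chain posterior for structural checks (not convergence claims)."""
    spec = mixing.build_mixing_spec(consumers, library)
    return spec, mixing.run_mcmc(spec, n_iter=2000, burn_in=1000,
                                 n_chains=3, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
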