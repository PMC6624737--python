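import numpy as np
import pytest

from thermoprobe import FluxParameters, SiteScenario, gen_microcosm_experiment


@pytest.fixture(scope="session")
def catabolic_params():
    return FluxParameters()


@pytest.fixture()
def noiseless_gas():
    """One-site microcosm bundle with zero instrument noise."""
    sc = SiteScenario("GBS85", 85.0, FluxParameters(), noise_sd=0.0)
    gas, manifest = gen_microcosm_experiment([sc], seed=11)
    return gas, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
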