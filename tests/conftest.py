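import numpy as np
import pytest

from funnelsig.model_core import ModelParams
from funnelsig.synthetic_data import gen_arms, gen_signature_catalog


@pytest.fixture(scope="session")
def efficient_params() -> ModelParams:
    """Reference efficient-regime parameter set used across oracle tests."""
    return ModelParams(f=1.0, b=5.0, r1=0.01, r2=10.0, N=10,
                       eps=0.01, eps_prime=0.05, p_tls=0.7, q_mmr=0.5, phi=0.1)


@pytest.fixture(scope="session")
def arms():
    return gen_arms(8, 50_000_000)


@pytest.fixture(scope="session")
def catalog():
    cat, _ = gen_signature_catalog(n_signatures=5, seed=11)
    return cat


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
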