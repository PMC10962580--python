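import numpy as np
import pytest

from baskex import ModelConfig, SamplerSettings, ve_basket_fixture


@pytest.fixture(scope="session")
def ve():
    """The packaged VE-BASKET trial data."""
    return ve_basket_fixture()


@pytest.fixture(scope="session")
def light_settings():
    """Short sampler runs for structural (non-reproduction) MCMC tests."""
    return SamplerSettings(chains=2, iterations=4_000, burn_in=2_000, seed=3)


@pytest.fixture(scope="session")
def ve_independent(ve):
    from baskex import fit_independent

    return fit_independent(ve)


@pytest.fixture(scope="session")
def ve_bma(ve):
    from baskex import fit_bma

    return fit_bma(ve)
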