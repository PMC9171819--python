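import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from chbe import cijfit

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ti_summary():
    return cijfit.load_ti_summary()


@pytest.fixture(scope="session")
def cij_reference():
    return cijfit.load_cij_reference().set_index("metal")


@pytest.fixture(scope="session")
def exp_dg(ti_summary):
    """Experimental binding energies keyed by (metal, chelator)."""
    return ti_summary.set_index(["metal", "chelator"]).dg_exp.to_dict()


@pytest.fixture(scope="session")
def edta_gradients():
    """Back-extrapolated EDTA gradient sets for the four metals."""
    return {m: cijfit.reference_gradient_set(m, "EDTA") for m in cijfit.METALS}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
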