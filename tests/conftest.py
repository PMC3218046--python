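import numpy as np
import pytest

from fretlin import synthetic_data as sd
from fretlin.ratiometric import ExcitationState
from fretlin.spectra import CoverageFractions


@pytest.fixture(scope="session")
def donor_spectrum():
    return sd.default_donor_spectrum()


@pytest.fixture(scope="session")
def acceptor_spectrum():
    return sd.default_acceptor_spectrum()


@pytest.fixture
def simple_cov():
    """Round-number capture coefficients used by the worked examples."""
    return CoverageFractions(f_DD=0.4, f_AD=0.1, f_AA=0.35)


@pytest.fixture
def unit_excitation():
    return ExcitationState(N_D_star=1000.0, N_A_direct=0.0, N_A_acc=1000.0)


@pytest.fixture
def noise_free():
    return sd.NoiseModel(intensity_cv=0.0, lifetime_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
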