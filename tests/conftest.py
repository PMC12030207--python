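import numpy as np
import pytest

from ibupbbm import dlm_dissolution as dlm
from ibupbbm.gi_pbpk import default_dispositions, default_gi_physiology


@pytest.fixture(scope="session")
def drug():
    return dlm.ibuprofen()


@pytest.fixture(scope="session")
def psd(drug):
    """Default polydisperse population at a test-friendly bin count."""
    return dlm.lognormal_psd(drug, d50_um=300.0, n_bins=10)


@pytest.fixture(scope="session")
def psd_small(drug):
    """Coarse 3-bin population for expensive in vivo simulations."""
    return dlm.lognormal_psd(drug, d50_um=300.0, n_bins=3)


@pytest.fixture(scope="session")
def buffer_protocol():
    return dlm.single_stage_protocol(6.5, volume_ml=900.0, duration_h=3.0)


@pytest.fixture(scope="session")
def two_stage():
    """Acid pretreatment (pH 2.0, 0.5 h) then maleate-type buffer pH 6.5."""
    return dlm.two_stage_protocol(2.0, 6.5, treatment_duration_h=2.5)


@pytest.fixture(scope="session")
def gi():
    return default_gi_physiology()


@pytest.fixture(scope="session")
def disp():
    return default_dispositions()
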