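import numpy as np
import pytest
from hypothesis import settings

from memsas import rbc

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def neutron_bilayer():
    return rbc.default_bilayer("neutron")


@pytest.fixture(scope="session")
def xray_bilayer():
    return rbc.default_bilayer("xray")


@pytest.fixture(scope="session")
def neutron_protein():
    return rbc.default_protein("neutron")


@pytest.fixture(scope="session")
def xray_protein():
    return rbc.default_protein("xray")


@pytest.fixture(scope="session")
def gauss_params():
    return rbc.default_gaussian()


@pytest.fixture(scope="session")
def fit_q():
    return np.geomspace(8e-3, 0.5, 60)
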