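import numpy as np
import pytest

from holoctf.material_table import blood_constants, material_entry
from holoctf.materials import cprime


@pytest.fixture(scope="session")
def blood():
    """Bundled water/hemoglobin blood-model optical constants (7.5 keV ref)."""
    return blood_constants()


@pytest.fixture(scope="session")
def paraffin():
    """Bundled paraffin optical constants."""
    return material_entry("paraffin")[1]


@pytest.fixture(scope="session")
def blood_cprime(blood):
    return cprime(blood)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
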