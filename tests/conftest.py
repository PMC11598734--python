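import numpy as np
import pytest
from hypothesis import settings

from leafoptics import LeafParams, fixture_spectra

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params() -> LeafParams:
    """Parameterized pea-leaf defaults (corrected pigments, s_Sp=600, F_S=0.15)."""
    return LeafParams()


@pytest.fixture(scope="session")
def initial_params() -> LeafParams:
    """Pre-correction parameter set (F_S=0, s_Sp=1000, uncorrected chlorophylls)."""
    return LeafParams(F_S=0.0, s_Sp=1000.0, C_ChA=2.77, C_ChB=1.69)


@pytest.fixture(scope="session")
def pigment_spectra():
    return fixture_spectra("gaussian_default")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
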