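import numpy as np
import pytest

from ringspec import model as mdl


@pytest.fixture(scope="session")
def toy_serine():
    return mdl.build_toy_serine()


@pytest.fixture(scope="session")
def ho_3000():
    """1-particle isotropic harmonic well at 3000 cm^-1, unit charge."""
    return mdl.build_harmonic_oscillator(1.0, 3000.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
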