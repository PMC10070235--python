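import numpy as np
import pytest

from excitonct.synthetic import toy_dimer


@pytest.fixture(scope="session")
def dimer():
    """Default slip-stacked toy dimer at 7 bohr."""
    return toy_dimer(separation=7.0)


@pytest.fixture(scope="session")
def mirror_dimer():
    """Eclipsed (mirror-symmetric) stack: no slip, identical fragments."""
    return toy_dimer(separation=7.0, slip=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
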