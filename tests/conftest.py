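import numpy as np
import pytest

from leukosim.fixtures import load_fixture


@pytest.fixture(scope="session")
def nominal():
    """The versioned calibrated fixture shipped with the package."""
    return load_fixture()


@pytest.fixture(scope="session")
def nominal_params(nominal):
    return nominal.params


@pytest.fixture(scope="session")
def nominal_equilibrium(nominal):
    return np.asarray(nominal.equilibrium)
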