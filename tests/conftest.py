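import numpy as np
import pytest

from sixmp.params import Patient
from sixmp.simulate import DoseRegimen


@pytest.fixture(scope="session")
def average_patient() -> Patient:
    return Patient()


@pytest.fixture(scope="session")
def standard_regimen() -> DoseRegimen:
    return DoseRegimen.daily(75, 112)


@pytest.fixture(scope="session")
def weekly_times() -> np.ndarray:
    return np.arange(7.0, 113.0, 7.0)
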