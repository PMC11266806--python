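import numpy as np
import pytest

from cytosim import dielectrics as dl
from cytosim.pipeline import default_size_calibration
from cytosim.signal_sim import ElectrodeConfig, NO_NOISE, TransitEvent, simulate_event


@pytest.fixture(scope="session")
def pbs():
    return dl.get_medium("PBS")


@pytest.fixture(scope="session")
def electrode():
    return ElectrodeConfig()


@pytest.fixture(scope="session")
def bead():
    return dl.get_preset("polystyrene", diameter_um=10.0)


@pytest.fixture(scope="session")
def wbc():
    return dl.get_preset("WBC")


@pytest.fixture(scope="session")
def mcf7():
    return dl.get_preset("MCF-7")


@pytest.fixture(scope="session")
def calibration(electrode):
    return default_size_calibration(electrode)


@pytest.fixture(scope="session")
def clean_bead_event(bead, electrode, pbs):
    """Noise-free T1 transit of a 10 um bead."""
    return simulate_event(TransitEvent(particle=bead), electrode, pbs, NO_NOISE)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
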