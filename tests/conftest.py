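import numpy as np
import pytest

from minicalor import load_sensor
from minicalor.synthetic import NoiseSpec

#: published parameter sets of the two minisensors (ground truth for round trips)
S1_TRUTH = {
    "K1": 117.98, "K2": -51.33, "K3": 8.98, "K4": 11.92,
    "tau1": 80.8, "tau2": 9.5,
    "tau1_star": 64.4, "tau2_star": 108.2, "tau3_star": 0.0, "tau4_star": 22.2,
}
S2_TRUTH = {
    "K1": 132.40, "K2": -42.22, "K3": 8.67, "K4": 9.82,
    "tau1": 84.0, "tau2": 8.2,
    "tau1_star": 73.5, "tau2_star": 96.1, "tau3_star": 0.0, "tau4_star": 18.4,
}

#: reference body-flux rows (Tcal degC -> A0, A1, A2 mW, tau1, tau2 s) from a
#: four-temperature hand series; used as ground truth for synthetic body runs
FLUX_ROWS = {
    24.0: (193.7, 1156.4, 101.0, 2.0, 21.2),
    28.0: (156.6, 779.3, 25.4, 3.1, 20.0),
    32.0: (110.4, 244.6, -21.6, 5.2, 120.0),
    36.0: (60.0, -35.6, -79.0, 1.0, 100.2),
}


@pytest.fixture(scope="session")
def s1():
    return load_sensor("S1")


@pytest.fixture(scope="session")
def s2():
    return load_sensor("S2")


@pytest.fixture()
def noiseless():
    return NoiseSpec.noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(20171128)
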