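import logging

import pytest

from inproice.thermo import ThermoParams

# the simulator's f_ice = 1 drop warnings are expected in bulk runs
logging.getLogger("inproice.spectra").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params() -> ThermoParams:
    return ThermoParams.default()


@pytest.fixture(scope="session")
def fixed_params() -> ThermoParams:
    """Hand-checkable constants: S12 = 1.2, v_ice = 3.25e-29 m^3, sigma12 = 0.03 J/m^2."""
    return ThermoParams.constant(s12=1.2, v_ice=3.25e-29, sigma12=0.03)
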