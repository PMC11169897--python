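import numpy as np
import pytest

from plasmopv.materials import DeviceScenario, bare_scenario


@pytest.fixture(scope="session")
def preferred_scenario() -> DeviceScenario:
    """r = 10 nm, f_s = 10%, 1.5-nm-gap cathode array, 453 nm, 0.26 mW/mm^2."""
    return DeviceScenario()


@pytest.fixture(scope="session")
def bare_453() -> DeviceScenario:
    return bare_scenario()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240530)
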