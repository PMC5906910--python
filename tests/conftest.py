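import numpy as np
import pytest

from fspherb.environment import LightSource
from fspherb.params import (HerbivoreParameters, LightParameters,
                            PlantParameters)


@pytest.fixture
def vertical_sun():
    """A single vertical direct source of 10 mol PAR m-2 d-1, R:FR 1.2."""
    return [LightSource(np.array([0.0, 0.0, -1.0]),
                        {"PAR": 10.0, "red": 10.0, "far_red": 10.0 / 1.2},
                        "direct")]


@pytest.fixture
def plant_params():
    return PlantParameters()


@pytest.fixture
def herb_params():
    return HerbivoreParameters()


@pytest.fixture
def light_params():
    return LightParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
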