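import logging
import warnings

import numpy as np
import pytest

from pftwin.bench import ScenarioConfig, make_femur_surface_mesh
from pftwin.geometry import GrooveParams, HeightFieldReference

logging.getLogger("pftwin").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message="open contact contour")


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def groove():
    return GrooveParams()


@pytest.fixture(scope="session")
def groove_reference(groove):
    return HeightFieldReference.from_groove(groove)


@pytest.fixture(scope="session")
def coarse_mesh(scenario):
    return make_femur_surface_mesh(scenario, "coarse")


@pytest.fixture(scope="session")
def fine_mesh(scenario):
    return make_femur_surface_mesh(scenario, "fine")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240223)
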