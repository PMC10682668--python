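import numpy as np
import pytest

from nirdry.fixtures import load_fixture
from nirdry.spectra import average_dishes
from nirdry.synth import DryingDesign, generate_study


@pytest.fixture(scope="session")
def mini_study():
    return load_fixture("mini_study")


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic drying study (2295 raw spectra), fixed seed."""
    return generate_study(DryingDesign(), master_seed=1)


@pytest.fixture(scope="session")
def averaged_study(default_study):
    return average_dishes(default_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
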