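import numpy as np
import pytest

from leafskel.pipeline import run_pipeline
from leafskel.synth import make_plant_front, make_plant_top


@pytest.fixture(scope="session")
def top_plant():
    return make_plant_top(8, rng_seed=0)


@pytest.fixture(scope="session")
def top_result(top_plant):
    return run_pipeline(top_plant.image, "top")


@pytest.fixture(scope="session")
def front_plant():
    return make_plant_front(6, rng_seed=1)


@pytest.fixture(scope="session")
def front_result(front_plant):
    return run_pipeline(front_plant.image, "front")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
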