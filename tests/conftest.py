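import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from capmoist.dielectric import MaterialConstants, SensorGeometry, structural_constants
from capmoist.synthetic import NoiseModel, generate_campaign


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def materials():
    return MaterialConstants()


@pytest.fixture(scope="session")
def sc(geometry, materials):
    return structural_constants(geometry, materials)


@pytest.fixture(scope="session")
def campaign():
    """Default-noise campaign with a fixed seed."""
    return generate_campaign(seed=0)


@pytest.fixture(scope="session")
def noiseless_campaign():
    return generate_campaign(noise=NoiseModel(sigma_capacitance=0.0), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
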