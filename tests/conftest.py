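import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from micromotor import RotationalScale, ThermalParams, translational_diffusion


@pytest.fixture(scope="session")
def thermal_defaults() -> ThermalParams:
    """1.00 um sphere in water-like solvent at 24 degC."""
    return ThermalParams()


@pytest.fixture(scope="session")
def rotational_defaults(thermal_defaults) -> RotationalScale:
    return RotationalScale.from_thermal(thermal_defaults)


@pytest.fixture(scope="session")
def d_t_defaults(thermal_defaults) -> float:
    return translational_diffusion(thermal_defaults)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
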