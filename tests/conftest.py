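import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gravipin import PinParameters, StatocyteGeometry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geom():
    """Wheat-coleoptile statocyte geometry: W=10d, H=25d, H_stato=4d."""
    return StatocyteGeometry()


@pytest.fixture(scope="session")
def pin_reduced():
    """Fig-7/8 parameter point: R=25, limiting pool, tau_PIN=13 min."""
    return PinParameters.from_reduced(R=25.0, P=1e-4, tau_pin=13.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
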