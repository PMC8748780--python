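import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemoflow import HankelBasis, SeriesControl, figure_defaults

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dp():
    """The fixed study conditions of the graphical analysis."""
    return figure_defaults()


@pytest.fixture(scope="session")
def ctrl():
    return SeriesControl(n_modes=40)


@pytest.fixture(scope="session")
def basis(ctrl):
    return HankelBasis.build(ctrl.n_modes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
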