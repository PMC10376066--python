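import numpy as np
import pytest
from hypothesis import settings

from fhrdyn.core_models import Cubic, FHRParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def ode_params():
    """Parameters of the ODE analysis sections (soft cubic, eps=0.1)."""
    return FHRParams(I=1.45, b=0.8, c=0.0, eps=0.1, cubic=Cubic.soft)


@pytest.fixture
def relaxation_params():
    """Small-eps relaxation regime used by the return-map construction."""
    return FHRParams(I=0.0, b=0.8, c=0.0, eps=0.01, cubic=Cubic.soft)


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)
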