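import numpy as np
import pytest

from silkabc.models import ScaledParameters, compile_model
from silkabc.synthetic import DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def map_params() -> ScaledParameters:
    """Published posterior-mode parameters of the preferred history."""
    return DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def constant_size_spec():
    """Effectively a single constant-size population: the split lies far
    beyond any realizable coalescence horizon and all sizes are 1."""
    p = ScaledParameters(theta1=0.01, ratio_theta2=1.0, ratio_thetaA=1.0,
                         ratio_thetaB1=1.0, ratio_thetaB2=1.0,
                         tauD=1e9, tau1=1e8, tau2=1e8)
    return compile_model(p, "A_no_flow")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
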