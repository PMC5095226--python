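import numpy as np
import pytest
from hypothesis import settings

from cellmotion import (Observations, ParameterSet, SpatialGrid,
                        TimePolynomial)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def grid():
    return SpatialGrid(100.0, 50)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def basic_params():
    return ParameterSet(
        alpha=TimePolynomial.constant(50.0, True),
        D_C=TimePolynomial.constant(5.0, True),
        gamma=TimePolynomial.constant(0.3, True),
        D_A=2.0, K_d=0.5, lam=0.2, C_max=10.0,
        attractant_init="uniform", A0=1.0)


@pytest.fixture
def toy_obs():
    return Observations(times=[0.0, 1.0],
                        groups=[[10.0, 50.0, 90.0], [20.0, 40.0, 60.0, 80.0]],
                        domain_length=100.0)

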