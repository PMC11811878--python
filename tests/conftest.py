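import math

import numpy as np
import pytest

from mtcortex import CylinderDomain, DynamicsParams
from mtcortex.flexibility import FlexibilityParams


@pytest.fixture
def domain():
    """Small protoxylem-like cylinder (R = 2 um, H = 24 um)."""
    return CylinderDomain(radius=2.0, height=24.0)


@pytest.fixture
def big_domain():
    """Effectively unbounded domain for isolated-tip experiments."""
    return CylinderDomain(radius=500.0, height=2e5)


@pytest.fixture
def dyn():
    """Representative protoxylem dynamics (bounded-growth regime)."""
    return DynamicsParams(
        v_plus=0.058, v_minus=0.085, v_tm=0.005,
        r_cat=0.0048, r_res=0.0063, r_sever=0.001,
    )


@pytest.fixture
def quiet_dyn():
    """No stochastic switching, no severing: purely geometric dynamics."""
    return DynamicsParams(
        v_plus=0.05, v_minus=0.08, v_tm=0.0, r_cat=0.0, r_res=0.0, r_sever=0.0,
    )


@pytest.fixture
def rigid():
    return FlexibilityParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
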