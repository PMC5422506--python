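import numpy as np
import pytest

from craniomat import fixtures as fx
from craniomat import reference as ref


@pytest.fixture
def suture():
    return ref.SUTURE


@pytest.fixture
def brain():
    return ref.BRAIN


@pytest.fixture
def dura():
    return ref.DURA


@pytest.fixture
def suture_curve():
    """Noise-free suture stress-stretch curve, 50 points on [1, 3]."""
    return fx.gen_uniaxial_curve(ref.SUTURE, (1.0, 3.0), n=50, noise_sd=0.0, seed=0)


@pytest.fixture
def haversine_pulse():
    """100 g, 10 ms single haversine impact pulse."""
    return fx.gen_acceleration_pulse("single", peak_g=100.0, duration_s=0.010)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
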