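import pytest

from soma_spt import BlinkModel, CameraModel, PSFModel

from helpers import make_trajectory


@pytest.fixture
def camera():
    return CameraModel(offset=100.0, gain=5.0)


@pytest.fixture
def psf():
    return PSFModel()  # sigma 1.2 px, 800 photons, 10 bg photons/px


@pytest.fixture
def never_blink():
    return BlinkModel(p_off=0.0, p_on=1.0)


@pytest.fixture
def traj_factory():
    return make_trajectory
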