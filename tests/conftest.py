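import numpy as np
import pytest

import stereogaze as sg


@pytest.fixture(scope="session")
def geometry():
    return sg.reference_rig()


@pytest.fixture(scope="session")
def eye():
    return sg.EyeParameters()


@pytest.fixture(scope="session")
def central_calib(geometry, eye):
    """Noiseless one-point calibration in direct-pupil imaging mode."""
    f1, f2 = sg.simulate_fixation(geometry, eye, (0.0, 0.0), n_frames=40)
    return sg.calibrate_one_point(f1, f2, geometry)


@pytest.fixture(scope="session")
def central_calib_snell(geometry, eye):
    """Noiseless one-point calibration with Snell-refracted pupil imaging."""
    f1, f2 = sg.simulate_fixation(geometry, eye, (0.0, 0.0), n_frames=40, mode="snell")
    return sg.calibrate_one_point(f1, f2, geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
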