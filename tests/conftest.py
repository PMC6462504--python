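"""Shared fixtures: a calibration brightness sample, the monomer PDF and
its autoconvolved n-mer components, and a default camera model.

Everything is generated programmatically with fixed seeds; session scope
keeps the KDE/FFT work from repeating across tests.
"""

import numpy as np
import pytest

from toccsl.mixture import build_components, estimate_monomer_pdf
from toccsl.simulate import draw_monomer_brightness
from toccsl.types import CameraModel

MONOMER_MEAN = 100.0
MONOMER_CV = 0.35


@pytest.fixture(scope="session")
def calib_samples():
    rng = np.random.default_rng(42)
    return draw_monomer_brightness(MONOMER_MEAN, MONOMER_CV, 5000, rng)


@pytest.fixture(scope="session")
def rho1(calib_samples):
    return estimate_monomer_pdf(calib_samples, n_max=5)


@pytest.fixture(scope="session")
def components(rho1):
    return build_components(rho1, 5)


@pytest.fixture()
def camera():
    return CameraModel()


@pytest.fixture()
def noiseless_camera():
    return CameraModel(offset=0.0, read_noise_sd=0.0, field_of_view=(32, 32))
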