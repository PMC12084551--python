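import numpy as np
import pytest

STAR_31 = """
data_optics

loop_
_rlnOpticsGroup
_rlnImagePixelSize
1 0.83

data_particles

loop_
_rlnMicrographName #1
_rlnCoordinateX #2
_rlnCoordinateY #3
_rlnAngleRot #4
_rlnAngleTilt #5
_rlnAnglePsi #6
_rlnHelicalTubeID #7
mic_a.mrc 100.0 200.0 10.0 90.0 45.0 1
mic_a.mrc 110.0 210.0 -20.0 90.0 45.0 1
mic_a.mrc 120.0 220.0 33.0 90.0 270.0 1
"""

STAR_30_FLAT = """
data_

loop_
_rlnMicrographName
_rlnCoordinateX
_rlnCoordinateY
_rlnAngleRot
_rlnAngleTilt
_rlnAnglePsi
_rlnHelicalTubeID
_rlnImagePixelSize
_rlnClassNumber
m1.mrc 10 20 0 90 0 1 1.1 7
m1.mrc 30 40 0 90 0 1 1.1 7
m1.mrc 12 21 0 88 180 2 1.1 3
m1.mrc 32 41 0 92 180 2 1.1 3
"""


@pytest.fixture
def star_31_text():
    return STAR_31


@pytest.fixture
def star_30_text():
    return STAR_30_FLAT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
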