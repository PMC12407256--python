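import numpy as np
import pytest

from msquant import (
    CalibrationDesign,
    NoiseModel,
    PeakShapeParams,
    ShapeDistribution,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return CalibrationDesign()


@pytest.fixture
def gaussian_shape():
    return PeakShapeParams(sigma=0.06)


@pytest.fixture
def silent_noise():
    return NoiseModel.silent()


@pytest.fixture
def shape_dist():
    return ShapeDistribution()
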