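import numpy as np
import pytest

from etpheno.chip_model import ChipGeometry, RTDCalibration
from etpheno.synthetic_study import StudyConfig


@pytest.fixture
def chip() -> ChipGeometry:
    return ChipGeometry()


@pytest.fixture
def calib() -> RTDCalibration:
    return RTDCalibration(r0=100.0, t0=25.0, alpha=2.2e-3)


@pytest.fixture
def noiseless_config() -> StudyConfig:
    return StudyConfig(noise_cv=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
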