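import numpy as np
import pytest

from pupilplr.params import PlrParams, StudyDesign


@pytest.fixture(scope="session")
def noiseless_params() -> PlrParams:
    return PlrParams(seed=11).noiseless()


@pytest.fixture(scope="session")
def default_params() -> PlrParams:
    return PlrParams(seed=11)


@pytest.fixture
def t_grid_15s() -> np.ndarray:
    return np.arange(0, 15.0, 0.01)


@pytest.fixture
def small_main_design() -> StudyDesign:
    return StudyDesign(phase="main", n_trials=32, sample_rate_hz=100.0)


@pytest.fixture
def small_validation_design() -> StudyDesign:
    return StudyDesign(phase="validation", sample_rate_hz=100.0)


@pytest.fixture
def small_calibration_design() -> StudyDesign:
    return StudyDesign(phase="calibration", sample_rate_hz=100.0, intensity_step=20.0)
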