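import numpy as np
import pytest

from chinooklipid.calibration import PiecewiseCalibration, predict_whole_body_lipid
from chinooklipid.synthetic_data import (
    default_calibration_config,
    default_survey_config,
    generate_calibration_set,
    generate_survey,
    reading_from_lipid,
)


@pytest.fixture(scope="session")
def published_cal():
    return PiecewiseCalibration.published()


@pytest.fixture(scope="session")
def calibration_samples():
    """Default synthetic homogenized cohort (63 fish, seed 0)."""
    return generate_calibration_set(default_calibration_config(seed=0))


@pytest.fixture(scope="session")
def survey_df():
    """Default synthetic survey (Table-3 sample sizes, seed 0)."""
    return generate_survey(default_survey_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_calibration_xy(n, noise_sd, seed, cal=None):
    """Readings plus noise-free/noisy lipid from the published curve.

    Whole-body lipid is drawn uniformly over the pre-image of the
    observed reading span, the reading is the exact inverse, and
    Gaussian noise of ``noise_sd`` (% lipid) is added to the response.
    """
    cal = cal or PiecewiseCalibration.published()
    r = np.random.default_rng(seed)
    lipid = r.uniform(2.0, 13.9, n)
    x = reading_from_lipid(lipid, cal)
    y = predict_whole_body_lipid(x, cal)
    if noise_sd > 0:
        y = y + r.normal(0.0, noise_sd, n)
    return x, y
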