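import numpy as np
import pytest

from irheat.heat_model import ThermalProfile
from irheat.thermometry import CalibrationCurve


@pytest.fixture
def profile():
    """Calibrated heat field: 4 C/mW, half-distance 11 um, ambient 20 C."""
    return ThermalProfile(slope_c_per_mw=4.0, half_distance_um=11.0, ambient_c=20.0)


@pytest.fixture
def calibration():
    """mCherry thermometer: 1.7 %/C anchored at 20 C over 15-40 C."""
    return CalibrationCurve(
        sensitivity_per_c=0.017,
        ref_temp_c=20.0,
        valid_range_c=(15.0, 40.0),
        fit_r_squared=1.0,
        n_points=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
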