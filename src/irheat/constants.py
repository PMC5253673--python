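"""Calibration constants for infrared single-cell heat-shock induction.

All values come from the in-vivo calibration of the mCherry thermometer and
the infrared laser heat field in *C. elegans* embryos.  Two slope values are
carried deliberately: the rounded value quoted in running text and the raw
regression slope from the power-vs-temperature fit.  Neither is silently
preferred; callers choose.
"""

import math

#: Fractional mCherry fluorescence decrease per °C (1.7 %/°C).
MCHERRY_SENSITIVITY_PER_C = 0.017

#: Temperature range over which the mCherry calibration is valid (°C).
CALIBRATION_RANGE_C = (15.0, 40.0)

#: Reference temperature for fluorescence normalization (°C).
REF_TEMP_C = 20.0

#: Focal heating slope, rounded value (°C per mW of laser power).
SLOPE_TEXT_C_PER_MW = 4.0

#: Focal heating slope from the linear regression of focus temperature on power.
SLOPE_FIT_C_PER_MW = 4.1

#: In-plane distance at which temperature elevation halves (μm).
HALF_DISTANCE_UM = 11.0

#: Heat-shock induction band: robust response with high viability (°C).
HEAT_SHOCK_BAND_C = (32.0, 34.0)

#: Standard induction duration (minutes of continuous irradiation).
INDUCTION_DURATION_MIN = 5.0

#: Time to reach thermal steady state after switching the laser (ms), and the
#: fraction of the asymptote that operationally defines "steady".
STEADY_STATE_MS = 500.0
STEADY_STATE_FRACTION = 0.95

#: First-order thermal response time constant (ms) such that the field reaches
#: STEADY_STATE_FRACTION of its asymptote at STEADY_STATE_MS.
DEFAULT_TAU_MS = STEADY_STATE_MS / math.log(1.0 / (1.0 - STEADY_STATE_FRACTION))

#: Pulsed ablation schedule that avoids off-target induction.
ABLATION_FREQUENCY_HZ = 6.0
ABLATION_PULSE_WIDTH_MS = 8.3
ABLATION_PEAK_POWER_MW = 13.0
ABLATION_DURATION_S = 10.0

#: Default lethal temperature for ablation planning (°C).  A convention:
#: prior one-second protocols computed at 50-70 °C caused immediate cell
#: disintegration, so 50 °C is taken as the lower edge of the lethal range.
DEFAULT_LETHAL_TEMP_C = 50.0
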