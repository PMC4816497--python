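"""Unit conversions.

Internally the simulator works in CGS (cm, g, s, dyne/cm^2) so that the
fluid constants (rho = 1.0 g/ml, grid spacing in cm) and the volumetric
penalty beta_s (printed in dyne/cm^2) live in one consistent system.
Material parameters and pressures are quoted in kPa and mmHg at the
configuration surface and converted here.
"""

KPA_TO_DYNE_CM2 = 1.0e4
MMHG_TO_DYNE_CM2 = 1333.22
ML_TO_CM3 = 1.0  # 1 ml == 1 cm^3
MM_TO_CM = 0.1


def kpa(value_kpa: float) -> float:
    """kPa -> dyne/cm^2."""
    return value_kpa * KPA_TO_DYNE_CM2


def to_kpa(value_dyne: float) -> float:
    """dyne/cm^2 -> kPa."""
    return value_dyne / KPA_TO_DYNE_CM2


def mmhg(value_mmhg: float) -> float:
    """mmHg -> dyne/cm^2."""
    return value_mmhg * MMHG_TO_DYNE_CM2


def to_mmhg(value_dyne: float) -> float:
    """dyne/cm^2 -> mmHg."""
    return value_dyne / MMHG_TO_DYNE_CM2
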