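"""Unit conversions used at the package boundary.

Everything internal is SI (m, Pa, s, m^3/s). Clinical inputs arrive in
mmHg, mm and L/min and are converted exactly once, at the interface.
"""

MMHG_TO_PA = 133.322
LPM_TO_M3S = 1.0e-3 / 60.0


def mmhg(p: float) -> float:
    """Pressure in mmHg -> Pa."""
    return p * MMHG_TO_PA


def to_mmhg(p_pa: float) -> float:
    """Pressure in Pa -> mmHg."""
    return p_pa / MMHG_TO_PA


def lpm(q: float) -> float:
    """Volumetric flow in L/min -> m^3/s."""
    return q * LPM_TO_M3S


def mm(x: float) -> float:
    """Length in mm -> m."""
    return x * 1.0e-3


def to_mm(x_m: float) -> float:
    """Length in m -> mm."""
    return x_m * 1.0e3
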