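"""Unit conventions and conversion factors.

All internal solver computation is in CGS (cm, s, g, dyne/cm^2, mL/s).
Pressures, stiffness (Eh/r0), Windkessel resistances and compliances cross
the public API in clinical units (mmHg, mmHg*s/mL, mL/mmHg), matching how
such quantities are reported in hemodynamics studies.
"""

#: dyne/cm^2 per mmHg
MMHG_TO_CGS: float = 1333.22

#: mmHg per dyne/cm^2
CGS_TO_MMHG: float = 1.0 / MMHG_TO_CGS


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Convert a pressure (or Eh/r0 stiffness) from mmHg to dyne/cm^2."""
    return p_mmhg * MMHG_TO_CGS


def cgs_to_mmhg(p_cgs: float) -> float:
    """Convert a pressure from dyne/cm^2 to mmHg."""
    return p_cgs * CGS_TO_MMHG


def resistance_to_cgs(r_mmhg_s_ml: float) -> float:
    """mmHg*s/mL -> dyne*s/cm^5."""
    return r_mmhg_s_ml * MMHG_TO_CGS


def compliance_to_cgs(c_ml_mmhg: float) -> float:
    """mL/mmHg -> cm^5/dyne."""
    return c_ml_mmhg / MMHG_TO_CGS
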