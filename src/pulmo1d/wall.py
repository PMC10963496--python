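"""Linear-elastic tube law and the analytic stiffness estimator.

The wall is modeled as a thin, linearly elastic, isotropic, incompressible
cylinder, which closes the 1D system with

    P(A) = (4/3) * K * (sqrt(A / A_dia) - 1) + P_dia,

where K = Eh/r0 (mmHg) lumps Young's modulus, wall thickness and reference
radius into a single stiffness, and (A_dia, P_dia) is the diastolic
reference state. K is reported in mmHg and converted to CGS inside the
solver. Given measured systolic/diastolic pressure and area pairs at the
MPA, K follows analytically by inverting the tube law at systole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import MMHG_TO_CGS

__all__ = [
    "WallModel",
    "pressure_from_area",
    "area_from_pressure",
    "estimate_stiffness",
    "wave_speed",
]


@dataclass(frozen=True)
class WallModel:
    """Tube-law parameters: K = Eh/r0 (mmHg), A_dia (cm^2), P_dia (mmHg)."""

    stiffness: float
    area_dia: float
    pressure_dia: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness K must be > 0")
        if self.area_dia <= 0:
            raise ValueError("A_dia must be > 0")

    @property
    def stiffness_cgs(self) -> float:
        return self.stiffness * MMHG_TO_CGS

    @property
    def collapse_pressure(self) -> float:
        """Lower pressure bound (mmHg) below which the tube law gives A <= 0."""
        return self.pressure_dia - 4.0 / 3.0 * self.stiffness


def pressure_from_area(wall: WallModel, area):
    """Transmural pressure (mmHg) at cross-sectional area A (cm^2)."""
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be > 0")
    p = (
        4.0 / 3.0 * wall.stiffness * (np.sqrt(a / wall.area_dia) - 1.0)
        + wall.pressure_dia
    )
    return float(p) if np.isscalar(area) else p


def area_from_pressure(wall: WallModel, pressure):
    """Exact algebraic inverse of the tube law.

    Valid for P above the collapse bound P_dia - (4/3)K, where the modeled
    area would reach zero; below that the linear tube law has no physical
    solution and a domain error is raised.
    """
    p = np.asarray(pressure, dtype=float)
    root = 1.0 + 3.0 * (p - wall.pressure_dia) / (4.0 * wall.stiffness)
    if np.any(root <= 0):
        raise ValueError(
            f"pressure at or below the collapse bound "
            f"{wall.collapse_pressure:.6g} mmHg"
        )
    a = wall.area_dia * root**2
    return float(a) if np.isscalar(pressure) else a


def estimate_stiffness(
    p_sys: float, p_dia: float, a_sys: float, a_dia: float
) -> float:
    """Analytic K = Eh/r0 (mmHg) from paired sys/dia pressure and area.

    Inverts the tube law evaluated at systole with the diastolic reference:
    K = (3/4) (P_sys - P_dia) / (sqrt(A_sys/A_dia) - 1). Substituting K back
    at A_sys reproduces P_sys exactly.
    """
    if p_sys <= p_dia:
        raise ValueError("need P_sys > P_dia")
    if a_dia <= 0:
        raise ValueError("need A_dia > 0")
    denom = math.sqrt(a_sys / a_dia) - 1.0
    if denom <= 0:
        raise ValueError(
            "A_sys <= A_dia: stiffness is undefined (degenerate area data)"
        )
    return 0.75 * (p_sys - p_dia) / denom


def wave_speed(wall: WallModel, area, rho: float = 1.03):
    """Pulse-wave speed c = sqrt(A/rho * dP/dA) (cm/s) from the tube law.

    With dP/dA = (2/3) K_cgs / sqrt(A * A_dia) this reduces to
    c = sqrt((2 K_cgs / 3 rho) * sqrt(A/A_dia)); c grows with A, i.e. the
    vessel stiffens under load.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be > 0")
    c = np.sqrt(
        2.0 * wall.stiffness_cgs / (3.0 * rho) * np.sqrt(a / wall.area_dia)
    )
    return float(c) if np.isscalar(area) else c
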