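"""Three-element Windkessel (WK3) outlet models.

Every terminal vessel of the segmented tree drains into a WK3 lumped model
(proximal resistance R_P, distal resistance R_D, compliance C) that stands
in for the unsegmented downstream bed, discharging toward a reference
outflow pressure set to the wedge pressure P_PCW.

Nominal parameterization from mean hemodynamics:
  * per terminal i, total resistance R_T(i) = (P_mean - P_PCW)/Qbar_i with
    Qbar_i from the Poiseuille mean-flow split; initially R_P = R_D = R_T/2;
  * total compliance from the diastolic exponential pressure decay,
    C_total = t_decay / (R_T_total * ln((P_sys-P_PCW)/(P_dia-P_PCW)));
  * C_total allocated to terminals in proportion to conductance 1/R_T(i),
    which keeps every terminal time constant R_T(i)*C_i equal — consistent
    with a single observed decay constant.

Network totals obey the parallel-circuit identities, and a global scaling
triple theta_wk = (r_P, r_D, c) multiplies every terminal uniformly during
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import ArterialNetwork, distribute_mean_flow

__all__ = [
    "Windkessel3",
    "WindkesselSet",
    "ScalingFactors",
    "nominal_windkessels",
    "total_compliance_from_decay",
    "distribute_compliance",
    "apply_scaling",
]

#: guard on the decay-formula log argument: below this the fitted decay is
#: too shallow to identify a compliance
_LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class Windkessel3:
    """One WK3 outlet: R_P, R_D (mmHg*s/mL), C (mL/mmHg), P_out (mmHg)."""

    r_prox: float
    r_dist: float
    compliance: float
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.r_prox < 0 or self.r_dist < 0:
            raise ValueError("resistances must be >= 0")
        if self.compliance <= 0:
            raise ValueError("compliance must be > 0")

    @property
    def r_total(self) -> float:
        return self.r_prox + self.r_dist


@dataclass(frozen=True)
class ScalingFactors:
    """Global Windkessel multipliers theta_wk = (r_P, r_D, c)."""

    r_prox: float = 1.0
    r_dist: float = 1.0
    compliance: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r_prox, self.r_dist, self.compliance) <= 0:
            raise ValueError("scaling factors must be > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r_prox, self.r_dist, self.compliance)


@dataclass
class WindkesselSet:
    """Terminal-id -> Windkessel3 map with parallel-combination totals."""

    elements: dict[str, Windkessel3]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty Windkessel set")

    @property
    def r_prox_total(self) -> float:
        return 1.0 / sum(1.0 / w.r_prox for w in self.elements.values())

    @property
    def r_dist_total(self) -> float:
        return 1.0 / sum(1.0 / w.r_dist for w in self.elements.values())

    @property
    def r_total(self) -> float:
        return 1.0 / sum(1.0 / w.r_total for w in self.elements.values())

    @property
    def c_total(self) -> float:
        return sum(w.compliance for w in self.elements.values())


def nominal_windkessels(
    net: ArterialNetwork,
    p_mean: float,
    p_pcw: float,
    q_root_mean: float,
    c_total: float | None = None,
) -> WindkesselSet:
    """Nominal WK3 set from mean pressure, wedge pressure and mean flow.

    R_T(i) = (p_mean - p_pcw)/Qbar_i, split evenly between R_P and R_D.
    If ``c_total`` is given it is distributed by terminal conductance;
    otherwise a unit total compliance is distributed (call
    :func:`distribute_compliance` later with the decay-derived total).
    """
    if p_mean <= p_pcw:
        raise ValueError("need P_mean > P_PCW (degenerate pressure data)")
    flows = distribute_mean_flow(net, q_root_mean)
    elements = {}
    for tid in net.terminals:
        r_t = (p_mean - p_pcw) / flows[tid]
        elements[tid] = Windkessel3(
            r_prox=0.5 * r_t, r_dist=0.5 * r_t, compliance=1.0, p_out=p_pcw
        )
    wks = WindkesselSet(elements)
    return distribute_compliance(c_total if c_total is not None else 1.0, wks)


def total_compliance_from_decay(
    p_sys: float,
    p_dia: float,
    p_pcw: float,
    t_decay: float,
    r_t_total: float,
) -> float:
    """Total compliance (mL/mmHg) from the diastolic exponential decay.

    Fitting P(t) - P_PCW = (P_sys - P_PCW) * exp(-t/(R_T_total*C_total))
    over a decay window of length ``t_decay`` that ends at P_dia gives
    C_total = t_decay / (R_T_total * ln((P_sys-P_PCW)/(P_dia-P_PCW))).
    """
    if not (p_sys > p_dia > p_pcw):
        raise ValueError("need P_sys > P_dia > P_PCW")
    if t_decay <= 0 or r_t_total <= 0:
        raise ValueError("t_decay and R_T_total must be > 0")
    log_arg = (p_sys - p_pcw) / (p_dia - p_pcw)
    log_val = math.log(log_arg)
    if log_val < _LOG_FLOOR:
        raise ValueError(
            "pulse pressure too small relative to P_PCW: decay-based "
            "compliance is unidentifiable"
        )
    return t_decay / (r_t_total * log_val)


def distribute_compliance(c_total: float, wks: WindkesselSet) -> WindkesselSet:
    """Allocate a total compliance to terminals by conductance 1/R_T(i).

    The allocation is normalized so the per-terminal compliances sum to
    ``c_total`` exactly, and equal-R_T terminals share equally.
    """
    if c_total <= 0:
        raise ValueError("C_total must be > 0")
    conds = {tid: 1.0 / w.r_total for tid, w in wks.elements.items()}
    total = sum(conds.values())
    elements = {
        tid: Windkessel3(
            r_prox=w.r_prox,
            r_dist=w.r_dist,
            compliance=c_total * conds[tid] / total,
            p_out=w.p_out,
        )
        for tid, w in wks.elements.items()
    }
    return WindkesselSet(elements)


def apply_scaling(wks: WindkesselSet, theta: ScalingFactors) -> WindkesselSet:
    """Scale every terminal by theta_wk = (r_P, r_D, c); totals follow."""
    elements = {
        tid: Windkessel3(
            r_prox=theta.r_prox * w.r_prox,
            r_dist=theta.r_dist * w.r_dist,
            compliance=theta.compliance * w.compliance,
            p_out=w.p_out,
        )
        for tid, w in wks.elements.items()
    }
    return WindkesselSet(elements)
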