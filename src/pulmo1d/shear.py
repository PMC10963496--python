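"""Power-law velocity profiles and wall-shear physiomarkers.

The 1D momentum closure assumes an axial velocity profile

    u(r) = Ubar * (gamma+2)/gamma * (1 - (r/R)^gamma),

whose cross-sectional average is Ubar = Q/A; gamma = 2 is Poiseuille flow
and larger gamma flattens the core. Differentiating at the wall gives the
wall shear stress magnitude |tau| = mu * (gamma+2) * |Ubar| / R, so shear
scales exactly with (gamma+2) at fixed flow and area.

From a converged cycle the module computes, per grid node and per vessel:

  * TAWSS = (1/T) int |tau| dt        (dyne/cm^2)
  * OSI   = 0.5 * (1 - |int tau dt| / int |tau| dt)   in [0, 0.5]
  * phi   = percentage of (by default intralobar) vessels with both
            TAWSS < 5 dyne/cm^2 and OSI > 0.05 — a thrombogenicity-
            related physiomarker.

tau carries the sign of Q so that OSI registers flow reversal; both
metrics are invariant to a global sign flip.

The gamma exponent itself can be fitted to radial velocity samples of the
kind extracted from 2D phase-contrast images (sector-averaged velocities
along the radius): candidate power-law profiles are matched to the
sample's flow and ranked by residual sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ArterialNetwork
from .solver import HemoState

__all__ = [
    "RadialProfileSample",
    "ShearSeries",
    "ShearReport",
    "powerlaw_profile",
    "wall_shear_from_state",
    "tawss",
    "osi",
    "phi_metric",
    "fit_gamma",
]

#: literature-based low-shear cutoff, dyne/cm^2
TAWSS_CUTOFF_DEFAULT = 5.0
#: high-oscillation cutoff (cohort-average OSI in the source data)
OSI_CUTOFF_DEFAULT = 0.05
GAMMA_CANDIDATES_DEFAULT = (2.0, 5.0, 7.0, 9.0)


@dataclass
class RadialProfileSample:
    """Sector-averaged velocity samples along a lumen radius.

    radii go from 0 (axis) to R (wall), velocities in cm/s; emulates the
    8-sector averaging of a 2D phase-contrast magnitude image.
    """

    radii: np.ndarray
    velocities: np.ndarray
    lumen_radius: float
    n_sectors: int = 8

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.radii.shape != self.velocities.shape:
            raise ValueError("radii and velocities must match in length")
        if np.any(self.radii < 0) or np.any(self.radii > self.lumen_radius):
            raise ValueError("radii must lie in [0, lumen_radius]")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    def flow(self) -> float:
        """Volumetric flow (mL/s) by annular (trapezoidal) quadrature."""
        order = np.argsort(self.radii)
        r = self.radii[order]
        v = self.velocities[order]
        return float(np.trapezoid(2.0 * np.pi * r * v, r))


@dataclass
class ShearSeries:
    """Signed wall shear tau(t) (dyne/cm^2) over one period, per node."""

    t: np.ndarray
    tau: np.ndarray  # shape (nt,) or (nt, nx)
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("shear values must be finite")


@dataclass
class ShearReport:
    """Per-vessel TAWSS/OSI table plus the network-level phi percentage."""

    table: pd.DataFrame  # columns: vessel, role, tawss, osi, low_tawss, high_osi
    phi: float
    tawss_cutoff: float
    osi_cutoff: float
    scope: str = "intralobar"


def powerlaw_profile(u_mean, lumen_radius: float, gamma: float, r):
    """Axial velocity u(r) of the power-law profile with average ``u_mean``.

    The disk average of u over 0 <= r <= R equals ``u_mean`` for any
    gamma > 0; u vanishes at the wall (no slip).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0) or np.any(rr > lumen_radius):
        raise ValueError("r must lie in [0, lumen_radius]")
    u = u_mean * (gamma + 2.0) / gamma * (1.0 - (rr / lumen_radius) ** gamma)
    return float(u) if np.isscalar(r) else u


def wall_shear_from_state(
    state: HemoState,
    mu: float,
    gamma: float,
    vessel_id: str | None = None,
) -> dict[str, ShearSeries] | ShearSeries:
    """Signed wall shear tau(x, t) from a converged cycle.

    tau = sign(Q) * mu * (gamma+2) * |Q/A| / R with R = sqrt(A/pi) — the
    wall derivative of the power-law profile, carrying the flow direction
    so oscillation metrics can detect reversal.
    """
    ids = [vessel_id] if vessel_id is not None else state.vessel_ids
    out = {}
    for vid in ids:
        a = state.area[vid]
        q = state.flow[vid]
        radius = np.sqrt(a / np.pi)
        tau = mu * (gamma + 2.0) * q / (a * radius)
        out[vid] = ShearSeries(t=state.t, tau=tau, period=state.period)
    return out[vessel_id] if vessel_id is not None else out


def tawss(series: ShearSeries) -> np.ndarray | float:
    """Time-averaged |tau| over one period (trapezoidal rule)."""
    val = np.trapezoid(np.abs(series.tau), series.t, axis=0) / series.period
    return float(val) if np.ndim(val) == 0 else val


def osi(series: ShearSeries) -> np.ndarray | float:
    """Oscillatory shear index in [0, 0.5].

    0 for unidirectional shear, 0.5 for zero-mean shear. Identically-zero
    shear has no defined oscillation; it is reported as 0 with a warning.
    """
    num = np.abs(np.trapezoid(series.tau, series.t, axis=0))
    den = np.trapezoid(np.abs(series.tau), series.t, axis=0)
    den_arr = np.atleast_1d(np.asarray(den, dtype=float))
    num_arr = np.atleast_1d(np.asarray(num, dtype=float))
    zero = den_arr == 0.0
    if np.any(zero):
        warnings.warn(
            "identically zero wall shear: OSI reported as 0", stacklevel=2
        )
    den_arr = np.where(zero, 1.0, den_arr)
    val = np.where(zero, 0.0, 0.5 * (1.0 - num_arr / den_arr))
    # clip quadrature round-off at the boundaries of [0, 0.5]
    val = np.clip(val, 0.0, 0.5)
    return float(val[0]) if np.ndim(den) == 0 else val


def vessel_shear_table(
    net: ArterialNetwork,
    state: HemoState,
    gamma: float | None = None,
    tawss_cutoff: float = TAWSS_CUTOFF_DEFAULT,
    osi_cutoff: float = OSI_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Length-averaged TAWSS and OSI per vessel, with cutoff flags."""
    gamma = net.gamma if gamma is None else gamma
    series = wall_shear_from_state(state, net.mu, gamma)
    rows = []
    for vid in state.vessel_ids:
        s = series[vid]
        tw_nodes = tawss(s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            osi_nodes = osi(s)
        x = state.x[vid]
        tw = float(np.trapezoid(tw_nodes, x) / (x[-1] - x[0]))
        ov = float(np.trapezoid(osi_nodes, x) / (x[-1] - x[0]))
        rows.append(
            {
                "vessel": vid,
                "role": net.vessels[vid].role,
                "length_cm": net.vessels[vid].length,
                "tawss": tw,
                "osi": ov,
                "low_tawss": tw < tawss_cutoff,
                "high_osi": ov > osi_cutoff,
            }
        )
    return pd.DataFrame(rows)


def phi_metric(
    table: pd.DataFrame,
    tawss_cutoff: float = TAWSS_CUTOFF_DEFAULT,
    osi_cutoff: float = OSI_CUTOFF_DEFAULT,
    scope: str = "intralobar",
    weight_by_length: bool = False,
) -> float:
    """Percentage of in-scope vessels with low TAWSS and high OSI.

    ``scope`` is 'intralobar' (default: the distal network where thrombus
    burden concentrates) or 'all'. With ``weight_by_length`` the share is
    computed over vessel length instead of vessel count.
    """
    if scope == "intralobar":
        sub = table[table["role"] == "intralobar"]
    elif scope == "all":
        sub = table
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if sub.empty:
        raise ValueError(f"no vessels in scope {scope!r}")
    qualifies = (sub["tawss"] < tawss_cutoff) & (sub["osi"] > osi_cutoff)
    if weight_by_length:
        return float(
            100.0
            * sub.loc[qualifies, "length_cm"].sum()
            / sub["length_cm"].sum()
        )
    return float(100.0 * qualifies.sum() / len(sub))


def shear_report(
    net: ArterialNetwork,
    state: HemoState,
    gamma: float | None = None,
    tawss_cutoff: float = TAWSS_CUTOFF_DEFAULT,
    osi_cutoff: float = OSI_CUTOFF_DEFAULT,
    scope: str = "intralobar",
) -> ShearReport:
    """Full per-vessel shear table plus the network phi percentage."""
    table = vessel_shear_table(net, state, gamma, tawss_cutoff, osi_cutoff)
    phi = phi_metric(table, tawss_cutoff, osi_cutoff, scope)
    return ShearReport(
        table=table,
        phi=phi,
        tawss_cutoff=tawss_cutoff,
        osi_cutoff=osi_cutoff,
        scope=scope,
    )


def fit_gamma(
    sample: RadialProfileSample,
    candidates: tuple[float, ...] = GAMMA_CANDIDATES_DEFAULT,
) -> tuple[float, dict[float, float]]:
    """Pick the power-law exponent that best matches a radial profile.

    For each candidate gamma, a power-law profile carrying the *same flow*
    as the sample (computed by annular quadrature) and zero wall velocity
    is generated, and the sum of squared velocity residuals is recorded.
    Returns (gamma_best, {gamma: SSE}).
    """
    if sample.radii.size < 4:
        raise ValueError("need at least 4 radial samples")
    q_sample = sample.flow()
    if q_sample <= 0:
        raise ValueError("non-positive sample flow: cannot match profiles")
    order = np.argsort(sample.radii)
    r = sample.radii[order]
    sse: dict[float, float] = {}
    for g in candidates:
        base = 1.0 - (sample.radii / sample.lumen_radius) ** g
        # scale the candidate so its flow, computed with the *same*
        # annular quadrature as the sample's, matches exactly
        q_base = float(np.trapezoid(2.0 * np.pi * r * base[order], r))
        u_model = q_sample / q_base * base
        sse[g] = float(np.sum((sample.velocities - u_model) ** 2))
    best = min(sse, key=sse.get)
    return best, sse
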