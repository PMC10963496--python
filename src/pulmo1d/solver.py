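"""Network pulse-wave solver: configuration, driver, and the HemoState result.

The driver packs an :class:`~pulmo1d.network.ArterialNetwork` plus wall and
Windkessel models into flat CGS arrays, chooses a stable time step, and
repeats cardiac cycles with the compiled Lax-Wendroff kernel until the
relative least-square difference between consecutive pressure cycles drops
below the configured tolerance. The returned :class:`HemoState` holds the
full space-time fields {P, A, Q} of the last (periodic) cycle per vessel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .network import ArterialNetwork, TimeSeries
from .units import MMHG_TO_CGS, CGS_TO_MMHG, resistance_to_cgs, compliance_to_cgs
from .wall import WallModel
from .windkessel import WindkesselSet

__all__ = [
    "SolverConfig",
    "HemoState",
    "SolverError",
    "ConvergenceError",
    "CFLError",
    "solve_to_periodic",
]


class SolverError(RuntimeError):
    """Generic solver failure (instability, Newton breakdown)."""


class ConvergenceError(SolverError):
    """Cycle-to-cycle periodicity not reached within max_cycles."""

    def __init__(self, msg: str, metric: float):
        super().__init__(msg)
        self.metric = metric


class CFLError(SolverError):
    """Stable time step not found above the dt floor."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the network solver.

    dx: nominal spatial step (cm); each vessel uses the nearest step that
        divides its length with at least 3 nodes.
    dt: initial time step (s); reduced automatically to satisfy the CFL
        condition with the given Courant number, halving down to dt_floor
        on observed violations.
    cycle_tolerance: relative least-square pressure difference between
        consecutive cycles below which the solution counts as periodic.
    """

    dx: float = 0.125
    dt: float = 1.0e-4
    cycle_tolerance: float = 1.0e-8
    max_cycles: int = 60
    cfl_number: float = 0.5
    #: give up once dt has been halved below this: a boundary Newton that
    #: still fails at a tiny Courant number is infeasible, not under-resolved
    dt_floor: float = 1.25e-5

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be > 0")
        if not 0.0 < self.cfl_number < 1.0:
            raise ValueError("CFL number must be in (0, 1)")


@dataclass
class HemoState:
    """Space-time fields of one converged cardiac cycle.

    ``t`` spans [0, T] inclusive (periodic endpoints); per-vessel fields
    are arrays of shape (len(t), n_nodes). Pressure is in mmHg, area in
    cm^2, flow in mL/s, and pressure/area are tube-law consistent at every
    node by construction.
    """

    t: np.ndarray
    period: float
    vessel_ids: list[str]
    x: dict[str, np.ndarray]
    area: dict[str, np.ndarray]
    flow: dict[str, np.ndarray]
    pressure: dict[str, np.ndarray]
    cycles_used: int = 0
    cycle_metric: float = float("nan")
    dt_used: float = float("nan")
    cfl_max: float = float("nan")

    def node_index(self, vid: str, s: float = 0.5) -> int:
        """Grid index closest to fractional position s in [0, 1]."""
        return int(round(s * (self.x[vid].size - 1)))

    def series(self, vid: str, which: str, s: float = 0.5) -> np.ndarray:
        """Time series of 'pressure'|'area'|'flow' at fractional position s."""
        return getattr(self, which)[vid][:, self.node_index(vid, s)]

    def timeseries(self, vid: str, which: str, s: float = 0.5) -> TimeSeries:
        return TimeSeries(
            times=self.t.copy(),
            values=self.series(vid, which, s).copy(),
            period=self.period,
        )


def _grid(net: ArterialNetwork, wall: WallModel, cfg: SolverConfig):
    """Pack network geometry into flat per-node CGS arrays."""
    order = [net.root.id]
    i = 0
    while i < len(order):
        order.extend(net.vessels[order[i]].children)
        i += 1
    vidx = {vid: k for k, vid in enumerate(order)}

    ns, dxs, Kv = [], [], []
    for vid in order:
        v = net.vessels[vid]
        n = max(3, int(round(v.length / cfg.dx)) + 1)
        ns.append(n)
        dxs.append(v.length / (n - 1))
        k_mmhg = v.stiffness if v.stiffness is not None else wall.stiffness
        Kv.append(k_mmhg * MMHG_TO_CGS)

    off = np.zeros(len(order) + 1, dtype=np.int64)
    off[1:] = np.cumsum(ns)
    moff = np.zeros(len(order) + 1, dtype=np.int64)
    moff[1:] = np.cumsum([n - 1 for n in ns])

    nn = int(off[-1])
    A0 = np.empty(nn)
    dA0 = np.zeros(nn)
    A0m = np.empty(int(moff[-1]))
    dA0m = np.zeros(int(moff[-1]))
    xs: dict[str, np.ndarray] = {}
    for k, vid in enumerate(order):
        v = net.vessels[vid]
        n = ns[k]
        x = np.linspace(0.0, v.length, n)
        xs[vid] = x
        a0 = np.asarray(v.area_dia(x), dtype=float)
        A0[off[k]: off[k + 1]] = a0
        # discrete derivatives of A0 chosen so that (A=A0, Q=0) is an exact
        # equilibrium of the discrete scheme
        dA0[off[k] + 1: off[k + 1] - 1] = (a0[2:] - a0[:-2]) / (2 * dxs[k])
        A0m[moff[k]: moff[k + 1]] = 0.5 * (a0[1:] + a0[:-1])
        dA0m[moff[k]: moff[k + 1]] = np.diff(a0) / dxs[k]

    return (
        order,
        vidx,
        off,
        moff,
        np.asarray(dxs),
        np.asarray(Kv),
        A0,
        dA0,
        A0m,
        dA0m,
        xs,
    )


def solve_to_periodic(
    net: ArterialNetwork,
    wall: WallModel,
    wks: WindkesselSet,
    q_mpa: TimeSeries,
    cfg: SolverConfig = SolverConfig(),
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
) -> HemoState:
    """Run cardiac cycles until the pressure field is periodic.

    q_mpa is the prescribed MPA inlet flow (mL/s) over one period; its
    endpoints must match to within 1% of the peak (periodicity check). The
    outlet set ``wks`` must cover exactly the network terminals.

    ``initial_state`` may carry (A, Q) flat arrays from a previous solve on
    the same grid to warm-start (used heavily during calibration).
    """
    # wrap jump between the last sample and the first: a periodic waveform
    # sampled on [0, T) must continue smoothly into the next cycle
    endpoints_gap = abs(float(q_mpa.values[-1]) - float(q_mpa.values[0]))
    peak = float(np.max(np.abs(q_mpa.values))) or 1.0
    if endpoints_gap > 0.01 * peak:
        raise ValueError(
            "inlet waveform is not periodic: endpoint mismatch "
            f"{endpoints_gap:.3g} exceeds 1% of peak {peak:.3g}"
        )
    if set(wks.elements) != set(net.terminals):
        raise ValueError(
            "Windkessel set does not match the network terminals"
        )

    (order, vidx, off, moff, dxs, Kv, A0, dA0, A0m, dA0m, xs) = _grid(
        net, wall, cfg
    )
    junctions = net.junctions
    jp = np.array([vidx[p] for p, _, _ in junctions], dtype=np.int64)
    jd1 = np.array([vidx[d] for _, d, _ in junctions], dtype=np.int64)
    jd2 = np.array([vidx[d] for _, _, d in junctions], dtype=np.int64)
    terms = net.terminals
    tvi = np.array([vidx[t] for t in terms], dtype=np.int64)
    Rp = np.array(
        [resistance_to_cgs(wks.elements[t].r_prox) for t in terms]
    )
    Rd = np.array(
        [resistance_to_cgs(wks.elements[t].r_dist) for t in terms]
    )
    Cw = np.array(
        [compliance_to_cgs(wks.elements[t].compliance) for t in terms]
    )
    pouts = {wks.elements[t].p_out for t in terms}
    if len(pouts) != 1:
        raise ValueError("all Windkessel outlets must share one P_out")
    pout = pouts.pop() * MMHG_TO_CGS
    pd = wall.pressure_dia * MMHG_TO_CGS

    T = q_mpa.period
    # initial dt: honor cfg.dt but respect an a-priori CFL estimate with
    # some headroom for systolic distension and velocity
    c_ref = max(
        math.sqrt(2.0 * k / (3.0 * net.rho)) for k in Kv
    )
    u_ref = peak / float(A0.min())
    dt = min(cfg.dt, cfg.cfl_number * float(dxs.min()) / (1.3 * c_ref + u_ref))

    if initial_state is not None:
        A_init, Q_init = initial_state
        if A_init.shape[0] != A0.shape[0]:
            raise ValueError("initial_state does not match the grid")
    else:
        A_init, Q_init = A0, np.zeros_like(A0)

    while True:
        steps = max(16, int(math.ceil(T / dt)))
        dt_eff = T / steps
        tk = np.arange(steps + 1) * dt_eff
        qin = np.asarray(q_mpa(tk), dtype=float)

        A = A_init.copy()
        Q = Q_init.copy()
        Astore = np.empty((steps, A.shape[0]))
        Qstore = np.empty((steps, A.shape[0]))

        p_prev = None
        metric = float("inf")
        failure = None
        cycles = 0
        s_max = 0.0
        for cycle in range(cfg.max_cycles):
            flag, s_max = _kernel.advance_cycle(
                A, Q, Astore, Qstore, off, moff, dxs, Kv, A0, dA0, A0m,
                dA0m, net.gamma, net.rho, net.mu, pd, jp, jd1, jd2, tvi,
                Rp, Rd, Cw, pout, qin, dt_eff,
            )
            cycles = cycle + 1
            if flag == _kernel.ERR_CFL or (
                flag == _kernel.OK and s_max > cfg.cfl_number
            ):
                failure = "cfl"
                break
            if flag == _kernel.ERR_NEG_AREA:
                failure = "negative_area"
                break
            if flag in (
                _kernel.ERR_NEWTON_INLET,
                _kernel.ERR_NEWTON_JUNCTION,
                _kernel.ERR_NEWTON_OUTLET,
            ):
                failure = ("newton_inlet", "newton_junction", "newton_outlet")[
                    flag - _kernel.ERR_NEWTON_INLET
                ]
                break
            p_cyc = _pressure_field(Astore, A0, off, Kv, pd)
            if p_prev is not None:
                metric = float(
                    np.sum((p_cyc - p_prev) ** 2) / np.sum(p_cyc**2)
                )
                if metric < cfg.cycle_tolerance:
                    break
            p_prev = p_cyc
        if failure is not None:
            # dt halving only helps when the failure is CFL-related; a
            # boundary Newton that breaks down far below the Courant limit
            # signals an infeasible parameter set, not under-resolution
            cfl_related = failure == "cfl" or s_max > 0.5 * cfg.cfl_number
            if not cfl_related or dt / 2.0 < cfg.dt_floor:
                raise CFLError(
                    f"unstable solve (failure: {failure}, Courant max "
                    f"{s_max:.3f}, dt {dt:g} s)"
                )
            dt /= 2.0
            continue
        if metric >= cfg.cycle_tolerance:
            raise ConvergenceError(
                f"not periodic after {cfg.max_cycles} cycles "
                f"(cycle metric {metric:.3e} >= {cfg.cycle_tolerance:g})",
                metric,
            )
        break

    # assemble the converged cycle with periodic endpoints: row 0 is the
    # state at t=0 (== end of the previous cycle == last stored row)
    t_out = np.concatenate(([0.0], tk[1:]))
    area, flow, pressure = {}, {}, {}
    p_full = _pressure_field(Astore, A0, off, Kv, pd)
    for k, vid in enumerate(order):
        sl = slice(int(off[k]), int(off[k + 1]))
        area[vid] = np.vstack([Astore[-1:, sl], Astore[:, sl]])
        flow[vid] = np.vstack([Qstore[-1:, sl], Qstore[:, sl]])
        pressure[vid] = np.vstack([p_full[-1:, sl], p_full[:, sl]])
    return HemoState(
        t=t_out,
        period=T,
        vessel_ids=list(order),
        x=xs,
        area=area,
        flow=flow,
        pressure=pressure,
        cycles_used=cycles,
        cycle_metric=metric,
        dt_used=dt_eff,
        cfl_max=s_max,
    )


def _pressure_field(Astore, A0, off, Kv, pd) -> np.ndarray:
    """Tube-law pressure (mmHg) for a stored area history."""
    p = np.empty_like(Astore)
    for k in range(off.shape[0] - 1):
        sl = slice(int(off[k]), int(off[k + 1]))
        p[:, sl] = (
            (4.0 / 3.0) * Kv[k] * (np.sqrt(Astore[:, sl] / A0[sl]) - 1.0)
            + pd
        )
    return p * CGS_TO_MMHG


def cyclic_mass_error(net: ArterialNetwork, state: HemoState) -> float:
    """Relative gap between inlet and summed terminal outflow volumes.

    Over one periodic cycle the storage terms cancel, so
    (int Q_in dt - sum_terminals int Q_out dt) / int Q_in dt measures the
    solver's cyclic mass-conservation error.
    """
    q_in = state.flow[net.root.id][:, 0]
    v_in = float(np.trapezoid(q_in, state.t))
    v_out = sum(
        float(np.trapezoid(state.flow[tid][:, -1], state.t))
        for tid in net.terminals
    )
    return abs(v_in - v_out) / abs(v_in)


def junction_residuals(
    net: ArterialNetwork, state: HemoState
) -> tuple[float, float]:
    """Worst relative mass and pressure-continuity residuals over junctions.

    Returns (mass_residual, pressure_residual), each normalized by the
    largest flow/pressure magnitude in the state.
    """
    q_scale = max(
        float(np.max(np.abs(q))) for q in state.flow.values()
    ) or 1.0
    p_scale = max(
        float(np.max(np.abs(p))) for p in state.pressure.values()
    ) or 1.0
    worst_q = 0.0
    worst_p = 0.0
    for parent, d1, d2 in net.junctions:
        qp = state.flow[parent][:, -1]
        q1 = state.flow[d1][:, 0]
        q2 = state.flow[d2][:, 0]
        pp = state.pressure[parent][:, -1]
        p1 = state.pressure[d1][:, 0]
        p2 = state.pressure[d2][:, 0]
        worst_q = max(worst_q, float(np.max(np.abs(qp - q1 - q2))))
        worst_p = max(
            worst_p,
            float(np.max(np.abs(pp - p1))),
            float(np.max(np.abs(pp - p2))),
        )
    return worst_q / q_scale, worst_p / p_scale


def state_to_frame(state: HemoState):
    """Flatten a HemoState into a tidy DataFrame (one row per node/time)."""
    import pandas as pd

    frames = []
    for vid in state.vessel_ids:
        x = state.x[vid]
        nt = state.t.size
        frames.append(
            pd.DataFrame(
                {
                    "vessel": vid,
                    "x_cm": np.tile(x, nt),
                    "t_s": np.repeat(state.t, x.size),
                    "P_mmHg": state.pressure[vid].ravel(),
                    "A_cm2": state.area[vid].ravel(),
                    "Q_ml_s": state.flow[vid].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
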