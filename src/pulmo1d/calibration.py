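"""Windkessel scaling-factor calibration against sparse subject data.

A subject-condition is summarized by a :class:`SubjectRecord`: MPA
systolic/diastolic pressure and area, wedge pressure, and one cycle of
flow waveforms at the MPA (model input) and at the LPA/RPA (calibration
targets). The forward model is fully determined by the network geometry,
the analytically estimated wall stiffness, and the nominal Windkessel set
scaled by the global triple theta_wk = (r_P, r_D, c); calibration infers
theta_wk by weighted nonlinear least squares

    S(theta) = w_P sum_j (P_j^c - P_j)^2 + w_A sum_j (A_j^c - A_j)^2
             + w_Q (1/N) sum_k sum_i (Q_k^c(t_i) - Q_k(t_i))^2,

j in {sys, dia}, k in {LPA, RPA}, with model pressures/areas read at the
MPA midpoint and flows at the branch midpoints. The default weights
normalize each block by the squared magnitude of its data (the printed
cost has unit weights despite mixed units; pass ``weights='unit'`` for
that literal form). Optimization runs trust-region least squares from ten
randomized (log-uniform) starting points and stops each start when the
parameters cease to change by more than 1e-6.

For obstructed (CTEPH) records the left-lung flow target is recomputed as
Qtilde_LPA(t) = Q_MPA(t) - Q_RPA(t), and the nominal left-lung Windkessel
distribution is rebalanced from the measured per-side mean flows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .network import ArterialNetwork, TimeSeries, Vessel
from .solver import (
    ConvergenceError,
    HemoState,
    SolverConfig,
    SolverError,
    solve_to_periodic,
)
from .wall import WallModel, estimate_stiffness
from .windkessel import (
    ScalingFactors,
    WindkesselSet,
    apply_scaling,
    distribute_compliance,
    nominal_windkessels,
    total_compliance_from_decay,
)

__all__ = [
    "SubjectRecord",
    "CalibrationResult",
    "recompute_left_flow",
    "model_from_record",
    "nominal_from_record",
    "cost",
    "calibrate",
    "fit_diagnostics",
]

log = logging.getLogger(__name__)

#: penalty magnitude (per residual element) when the forward solve fails
_PENALTY = 1.0e3
#: multistart draw range for each scaling factor
THETA_RANGE = (0.1, 10.0)


@dataclass
class SubjectRecord:
    """Measured (or synthetic) data bundle for one subject-condition.

    Pressures in mmHg, areas in cm^2, flows in mL/s. ``t_decay`` is the
    diastolic window length (s) used for the decay-based compliance
    estimate; it is part of the measurement protocol, not a fit product.
    """

    p_sys: float
    p_dia: float
    p_pcw: float
    a_sys: float
    a_dia: float
    q_mpa: TimeSeries
    q_lpa: TimeSeries
    q_rpa: TimeSeries
    condition: str = "baseline"
    t_decay: float | None = None

    def __post_init__(self) -> None:
        if self.p_sys <= self.p_dia:
            raise ValueError("need P_sys > P_dia")
        if self.a_sys < self.a_dia:
            raise ValueError("need A_sys >= A_dia")
        if self.condition not in ("baseline", "CTEPH"):
            raise ValueError("condition must be 'baseline' or 'CTEPH'")
        periods = {self.q_mpa.period, self.q_lpa.period, self.q_rpa.period}
        if max(periods) - min(periods) > 0.01 * max(periods):
            raise ValueError("flow series periods differ by more than 1%")
        if self.t_decay is None:
            self.t_decay = 0.6 * self.q_mpa.period

    @property
    def period(self) -> float:
        return self.q_mpa.period

    @property
    def mpap(self) -> float:
        """Weighted mean MPA pressure 1/3 P_sys + 2/3 P_dia."""
        return self.p_sys / 3.0 + 2.0 * self.p_dia / 3.0


@dataclass
class CalibrationResult:
    theta_best: ScalingFactors
    cost_best: float
    starts: list[dict] = field(default_factory=list)
    all_agree: bool = False
    agreement_spread: float = float("nan")
    diagnostics: dict = field(default_factory=dict)
    converged: bool = False


def recompute_left_flow(
    q_mpa: TimeSeries, q_rpa: TimeSeries
) -> TimeSeries:
    """Left-lung flow as the mass-balance difference Q_MPA - Q_RPA.

    Used for obstructed records where poor contrast makes the directly
    measured left-side flow unreliable. Series are resampled onto the
    right-side time grid by periodic linear interpolation.
    """
    if abs(q_mpa.period - q_rpa.period) > 0.01 * q_rpa.period:
        raise ValueError("flow series periods differ by more than 1%")
    vals = np.asarray(q_mpa(q_rpa.times), dtype=float) - q_rpa.values
    return TimeSeries(
        times=q_rpa.times.copy(), values=vals, period=q_rpa.period
    )


def _clone_network(net: ArterialNetwork) -> ArterialNetwork:
    vessels = {
        vid: Vessel(
            id=v.id,
            name=v.name,
            role=v.role,
            length=v.length,
            inlet_radius=v.inlet_radius,
            outlet_radius=v.outlet_radius,
            stiffness=v.stiffness,
            parent=v.parent,
            children=v.children,
            windkessel=dict(v.windkessel) if v.windkessel else None,
        )
        for vid, v in net.vessels.items()
    }
    return ArterialNetwork(
        vessels=vessels, rho=net.rho, mu=net.mu, gamma=net.gamma
    )


def model_from_record(
    net: ArterialNetwork, record: SubjectRecord
) -> tuple[ArterialNetwork, WallModel]:
    """Anchor the model to a record's diastolic reference state.

    Returns a copy of the network whose MPA reference area at the
    measurement plane (vessel midpoint) matches the measured diastolic
    area, plus the wall model with the analytically estimated stiffness
    and the measured (P_dia, A_dia) reference. Uniform stiffness is used
    network-wide (a single Eh/r0 is reported per subject-condition);
    per-vessel overrides present in the network file are preserved.
    """
    k_est = estimate_stiffness(
        record.p_sys, record.p_dia, record.a_sys, record.a_dia
    )
    out = _clone_network(net)
    mpa = out.root
    a_mid = float(mpa.area_dia(0.5 * mpa.length))
    out.scale_areas(record.a_dia / a_mid, roles=("MPA",))
    wall = WallModel(
        stiffness=k_est,
        area_dia=record.a_dia,
        pressure_dia=record.p_dia,
    )
    return out, wall


def _side_roots(net: ArterialNetwork) -> tuple[str, str]:
    """(left, right) daughter ids of the MPA, identified by role."""
    d1, d2 = net.root.children
    roles = {net.vessels[d1].role: d1, net.vessels[d2].role: d2}
    if "LPA" in roles and "RPA" in roles:
        return roles["LPA"], roles["RPA"]
    return d1, d2


def nominal_from_record(
    net: ArterialNetwork, record: SubjectRecord
) -> WindkesselSet:
    """Nominal Windkessel set parameterized from a subject record.

    Per-terminal resistances follow the Poiseuille mean-flow split of the
    record's mean MPA flow; for obstructed records the split at the first
    junction is replaced by the measured per-side mean flows (right side
    measured, left side from the mass-balance difference), since the
    obstruction invalidates the purely geometric split. Total compliance
    comes from the diastolic pressure decay and is distributed by terminal
    conductance.
    """
    q_mean = record.q_mpa.mean
    p_mean = record.mpap
    wks = nominal_windkessels(net, p_mean, record.p_pcw, q_mean)
    if record.condition == "CTEPH":
        q_left = recompute_left_flow(record.q_mpa, record.q_rpa).mean
        q_right = record.q_rpa.mean
        # rebalance per-side terminal resistances to the measured shares
        lpa, rpa = _side_roots(net)
        shares = {
            tid: q_left / (q_left + q_right)
            for tid in net.downstream_terminals(lpa)
        }
        shares.update(
            {
                tid: q_right / (q_left + q_right)
                for tid in net.downstream_terminals(rpa)
            }
        )
        elements = {}
        for side in (lpa, rpa):
            sub_terms = net.downstream_terminals(side)
            # Poiseuille split within the side, scaled to the side share
            side_flow = q_mean * shares[sub_terms[0]]
            sub_flows = _subtree_flows(net, side, side_flow)
            for tid in sub_terms:
                r_t = (p_mean - record.p_pcw) / sub_flows[tid]
                w = wks.elements[tid]
                elements[tid] = replace(
                    w, r_prox=0.5 * r_t, r_dist=0.5 * r_t
                )
        wks = WindkesselSet(elements)
    c_total = total_compliance_from_decay(
        record.p_sys,
        record.p_dia,
        record.p_pcw,
        record.t_decay,
        wks.r_total,
    )
    return distribute_compliance(c_total, wks)


def _subtree_flows(
    net: ArterialNetwork, root_id: str, q_root: float
) -> dict[str, float]:
    """Poiseuille mean-flow split restricted to the subtree at root_id."""
    from .network import poiseuille_conductance

    flows = {root_id: q_root}
    stack = [root_id]
    while stack:
        vid = stack.pop()
        v = net.vessels[vid]
        if not v.children:
            continue
        d1, d2 = v.children
        f1 = poiseuille_conductance(net.vessels[d1], net.mu)
        f2 = poiseuille_conductance(net.vessels[d2], net.mu)
        flows[d1] = flows[vid] * f1 / (f1 + f2)
        flows[d2] = flows[vid] * f2 / (f1 + f2)
        stack.extend(v.children)
    return flows


def flow_targets(record: SubjectRecord) -> tuple[TimeSeries, TimeSeries]:
    """(left, right) calibration flow series for this record.

    Obstructed records substitute the recomputed left-lung flow."""
    if record.condition == "CTEPH":
        return recompute_left_flow(record.q_mpa, record.q_rpa), record.q_rpa
    return record.q_lpa, record.q_rpa


def _model_observables(
    net: ArterialNetwork, state: HemoState, record: SubjectRecord
):
    """Model counterparts of the measured scalars and branch flows.

    Systolic pressure/area are cycle maxima at the MPA midplane;
    diastolic values are end-diastolic (cycle start, the onset of
    ejection). Branch flows are read at the LPA/RPA inlet planes (just
    distal to the bifurcation, where phase-contrast planes are placed),
    which also keeps the mass-balance surrogate Q_MPA - Q_RPA close to
    the left-side flow. Conventions match the measurement emulation."""
    lpa, rpa = _side_roots(net)
    p = state.series(net.root.id, "pressure", 0.5)
    a = state.series(net.root.id, "area", 0.5)
    q_l = np.interp(
        record.q_lpa.times,
        state.t,
        state.series(lpa, "flow", 0.0),
    )
    q_r = np.interp(
        record.q_rpa.times,
        state.t,
        state.series(rpa, "flow", 0.0),
    )
    return (
        float(p.max()),
        float(p[0]),
        float(a.max()),
        float(a[0]),
        q_l,
        q_r,
    )


def _residuals(
    net: ArterialNetwork,
    state: HemoState,
    record: SubjectRecord,
    weights: str,
) -> np.ndarray:
    p_sys_m, p_dia_m, a_sys_m, a_dia_m, q_l_m, q_r_m = _model_observables(
        net, state, record
    )
    q_left_d, q_right_d = flow_targets(record)
    q_l_d = np.asarray(q_left_d(record.q_lpa.times), dtype=float)
    q_r_d = np.asarray(q_right_d(record.q_rpa.times), dtype=float)
    n = q_l_d.size
    if weights == "normalized":
        s_p = max(abs(record.p_sys), abs(record.p_dia))
        s_a = max(abs(record.a_sys), abs(record.a_dia))
        s_q = max(
            float(np.max(np.abs(q_l_d))), float(np.max(np.abs(q_r_d))), 1e-12
        )
    elif weights == "unit":
        s_p = s_a = s_q = 1.0
    else:
        raise ValueError("weights must be 'normalized' or 'unit'")
    return np.concatenate(
        [
            [
                (p_sys_m - record.p_sys) / s_p,
                (p_dia_m - record.p_dia) / s_p,
                (a_sys_m - record.a_sys) / s_a,
                (a_dia_m - record.a_dia) / s_a,
            ],
            (q_l_m - q_l_d) / (s_q * math.sqrt(n)),
            (q_r_m - q_r_d) / (s_q * math.sqrt(n)),
        ]
    )


class _ForwardCache:
    """Warm-start store: reuse the last converged state per theta walk."""

    def __init__(self):
        self.state: tuple[np.ndarray, np.ndarray] | None = None


def _forward(
    net: ArterialNetwork,
    wall: WallModel,
    wks_nominal: WindkesselSet,
    theta: ScalingFactors,
    record: SubjectRecord,
    cfg: SolverConfig,
    cache: _ForwardCache | None = None,
) -> HemoState:
    wks = apply_scaling(wks_nominal, theta)
    init = cache.state if cache is not None else None
    try:
        state = solve_to_periodic(
            net, wall, wks, record.q_mpa, cfg, initial_state=init
        )
    except ConvergenceError:
        if init is None:
            raise
        # a stale warm start can stall convergence for a distant theta;
        # hard instabilities are theta's fault and are not retried
        state = solve_to_periodic(net, wall, wks, record.q_mpa, cfg)
    if cache is not None:
        vid0 = state.vessel_ids
        a = np.concatenate([state.area[v][-1] for v in vid0])
        q = np.concatenate([state.flow[v][-1] for v in vid0])
        cache.state = (a, q)
    return state


def cost(
    theta: ScalingFactors,
    net: ArterialNetwork,
    wall: WallModel,
    wks_nominal: WindkesselSet,
    record: SubjectRecord,
    cfg: SolverConfig = SolverConfig(),
    weights: str = "normalized",
) -> float:
    """Scalar calibration cost S(theta) for one subject record."""
    state = _forward(net, wall, wks_nominal, theta, record, cfg)
    r = _residuals(net, state, record, weights)
    return float(np.sum(r**2))


def calibrate(
    net: ArterialNetwork,
    record: SubjectRecord,
    cfg: SolverConfig = SolverConfig(),
    n_starts: int = 10,
    seed: int = 0,
    weights: str = "normalized",
    xtol: float = 1.0e-6,
    agreement_tol: float = 1.0e-3,
    diff_step: float = 0.02,
) -> CalibrationResult:
    """Infer theta_wk by multi-start trust-region least squares.

    Starting points are log-uniform draws from [0.1, 10]^3 (seeded); the
    optimization runs in log10(theta) so positivity is built in and the
    1e-6 parameter-change stopping rule acts on relative changes. The
    result records whether all converged starts agree to within
    ``agreement_tol`` relative spread.
    """
    model_net, wall = model_from_record(net, record)
    wks_nominal = nominal_from_record(model_net, record)

    rng = np.random.default_rng(seed)
    lo, hi = math.log10(THETA_RANGE[0]), math.log10(THETA_RANGE[1])
    starts = rng.uniform(lo, hi, size=(n_starts, 3))

    cache = _ForwardCache()

    n_res = 4 + record.q_lpa.times.size * 2

    def penalty(log_theta: np.ndarray) -> np.ndarray:
        # sloped toward theta = 1 so the optimizer is pushed back out of
        # the infeasible corner instead of stalling on a flat plateau
        mag = float(np.nansum(np.abs(log_theta)))
        return np.full(n_res, _PENALTY * (1.0 + mag))

    def residual_fn(log_theta: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(log_theta)):
            return penalty(log_theta)
        theta = ScalingFactors(*(10.0**log_theta))
        try:
            state = _forward(
                model_net, wall, wks_nominal, theta, record, cfg, cache
            )
        except SolverError as exc:
            log.warning("forward solve failed at theta=%s: %s", theta, exc)
            return penalty(log_theta)
        return _residuals(model_net, state, record, weights)

    outcomes = []
    for si, x0 in enumerate(starts):
        cache.state = None
        try:
            fit = least_squares(
                residual_fn,
                x0,
                method="trf",
                bounds=(lo - 1.0, hi + 1.0),
                xtol=xtol,
                ftol=None,
                gtol=None,
                diff_step=diff_step,
            )
            outcomes.append(
                {
                    "start": 10.0**x0,
                    "theta": 10.0**fit.x,
                    "cost": float(2.0 * fit.cost),  # least_squares halves
                    "converged": bool(fit.success),
                    "nfev": int(fit.nfev),
                    "message": fit.message,
                }
            )
        except Exception as exc:  # keep the multistart alive
            log.warning("start %d failed: %s", si, exc)
            outcomes.append(
                {
                    "start": 10.0**x0,
                    "theta": None,
                    "cost": float("inf"),
                    "converged": False,
                    "nfev": 0,
                    "message": str(exc),
                }
            )

    good = [o for o in outcomes if o["theta"] is not None]
    if not good:
        raise RuntimeError(
            "calibration failed: no start converged "
            f"({[o['message'] for o in outcomes]})"
        )
    best = min(good, key=lambda o: o["cost"])
    thetas = np.array([o["theta"] for o in good if o["converged"]])
    if thetas.size:
        spread = float(
            np.max(
                np.abs(thetas - np.asarray(best["theta"]))
                / np.asarray(best["theta"])
            )
        )
    else:
        spread = float("nan")
    theta_best = ScalingFactors(*best["theta"])

    final_state = _forward(
        model_net, wall, wks_nominal, theta_best, record, cfg
    )
    diags = fit_diagnostics(model_net, final_state, record)
    return CalibrationResult(
        theta_best=theta_best,
        cost_best=best["cost"],
        starts=outcomes,
        all_agree=bool(
            thetas.shape[0] == len(good) and spread <= agreement_tol
        ),
        agreement_spread=spread,
        diagnostics=diags,
        converged=best["converged"],
    )


def fit_diagnostics(
    net: ArterialNetwork, state: HemoState, record: SubjectRecord
) -> dict:
    """Relative scalar errors and branch-flow R^2 for a converged state.

    Relative error is (model - data)/data; R^2 = 1 - SS_res/SS_tot per
    branch flow series (left target is the recomputed difference flow for
    obstructed records).
    """
    p_sys_m, p_dia_m, a_sys_m, a_dia_m, q_l_m, q_r_m = _model_observables(
        net, state, record
    )
    q_left_d, q_right_d = flow_targets(record)
    q_l_d = np.asarray(q_left_d(record.q_lpa.times), dtype=float)
    q_r_d = np.asarray(q_right_d(record.q_rpa.times), dtype=float)

    def r2(data, model):
        ss_tot = float(np.sum((data - data.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("zero-variance flow series: R^2 undefined")
        return 1.0 - float(np.sum((data - model) ** 2)) / ss_tot

    return {
        "rel_err_p_sys": (p_sys_m - record.p_sys) / record.p_sys,
        "rel_err_p_dia": (p_dia_m - record.p_dia) / record.p_dia,
        "rel_err_a_sys": (a_sys_m - record.a_sys) / record.a_sys,
        "rel_err_a_dia": (a_dia_m - record.a_dia) / record.a_dia,
        "r2_q_lpa": r2(q_l_d, q_l_m),
        "r2_q_rpa": r2(q_r_d, q_r_m),
    }
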