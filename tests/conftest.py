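"""Shared fixtures: small networks, converged states, virtual subjects.

Expensive artifacts (periodic solves, virtual subjects, the calibrated
cohort) are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from pulmo1d import (
    ArterialNetwork,
    ScalingFactors,
    SolverConfig,
    TimeSeries,
    Vessel,
    WallModel,
    Windkessel3,
    WindkesselSet,
    nominal_windkessels,
    solve_to_periodic,
)
from pulmo1d.synthetic import TreeSpec, make_virtual_subject


def single_vessel_network(gamma: float, length: float = 5.0,
                          radius: float = 0.5) -> ArterialNetwork:
    v = Vessel(
        id="MPA", role="MPA", length=length,
        inlet_radius=radius, outlet_radius=radius,
    )
    return ArterialNetwork(vessels={"MPA": v}, gamma=gamma)


def three_vessel_network(gamma: float = 5.0) -> ArterialNetwork:
    vessels = {
        "MPA": Vessel(id="MPA", role="MPA", length=3.5, inlet_radius=0.7,
                      outlet_radius=0.65, children=("LPA", "RPA")),
        "LPA": Vessel(id="LPA", role="LPA", length=2.5, inlet_radius=0.5,
                      outlet_radius=0.45, parent="MPA"),
        "RPA": Vessel(id="RPA", role="RPA", length=2.5, inlet_radius=0.55,
                      outlet_radius=0.5, parent="MPA"),
    }
    return ArterialNetwork(vessels=vessels, gamma=gamma)


def pulsatile_inflow(period: float = 0.5, t_sys: float = 0.2,
                     peak: float = 60.0, n: int = 128) -> TimeSeries:
    t = np.linspace(0.0, period, n, endpoint=False)
    q = np.where(t < t_sys, peak * np.sin(np.pi * t / t_sys), 0.0)
    return TimeSeries(times=t, values=q, period=period)


@pytest.fixture(scope="session")
def default_wall() -> WallModel:
    return WallModel(stiffness=56.25, area_dia=np.pi * 0.25,
                     pressure_dia=15.0)


@pytest.fixture(scope="session")
def steady_single_vessel_states(default_wall):
    """Converged steady-flow states for gamma=2 and gamma=5.

    The outlet reference pressure is chosen so the vessel operates near
    its reference area, where the friction-gradient oracles apply."""
    states = {}
    q0 = 10.0
    r_tot = 0.04
    t = np.linspace(0, 0.5, 64, endpoint=False)
    q = TimeSeries(times=t, values=np.full(64, q0), period=0.5)
    for gamma in (2.0, 5.0):
        net = single_vessel_network(gamma)
        wk = WindkesselSet({
            "MPA": Windkessel3(r_prox=r_tot / 2, r_dist=r_tot / 2,
                               compliance=0.5, p_out=15.0 - q0 * r_tot)
        })
        states[gamma] = (
            net,
            solve_to_periodic(
                net, default_wall, wk, q,
                SolverConfig(cycle_tolerance=1e-10),
            ),
        )
    return states


@pytest.fixture(scope="session")
def pulsatile_three_vessel(default_wall):
    """Converged pulsatile state on the 3-vessel tree (conservation suite)."""
    net = three_vessel_network()
    wall = WallModel(stiffness=40.0, area_dia=np.pi * 0.49,
                     pressure_dia=12.0)
    q = pulsatile_inflow()
    wks = nominal_windkessels(net, p_mean=16.0, p_pcw=5.0,
                              q_root_mean=q.mean, c_total=1.5)
    state = solve_to_periodic(
        net, wall, wks, q, SolverConfig(cycle_tolerance=1e-8)
    )
    return net, wall, wks, q, state


@pytest.fixture(scope="session")
def coarse_cfg() -> SolverConfig:
    return SolverConfig(dx=0.25, dt=2.0e-4, cycle_tolerance=1e-9)


@pytest.fixture(scope="session")
def virtual_subject(coarse_cfg):
    """Noiseless 7-vessel virtual subject with known scaling factors."""
    return make_virtual_subject(
        tree_spec=TreeSpec(generations=3),
        theta_truth=ScalingFactors(1.3, 0.7, 1.5),
        noise=0.0,
        seed=0,
        solver_config=coarse_cfg,
    )


@pytest.fixture(scope="session")
def noisy_baseline_record(virtual_subject):
    """Baseline record with 2% seeded Gaussian noise on the branch flows.

    The noise emulates phase-contrast flow measurement error (std = 2% of
    the waveform peak, per frame); catheter-derived pressures and the
    anchoring areas are left exact."""
    from pulmo1d.calibration import SubjectRecord

    rec = virtual_subject.baseline_record
    rng = np.random.default_rng(0)

    def noisy(ts):
        sigma = 0.02 * float(np.max(np.abs(ts.values)))
        return TimeSeries(
            times=ts.times.copy(),
            values=ts.values + rng.normal(0.0, sigma, ts.values.shape),
            period=ts.period,
        )

    return SubjectRecord(
        p_sys=rec.p_sys, p_dia=rec.p_dia, p_pcw=rec.p_pcw,
        a_sys=rec.a_sys, a_dia=rec.a_dia,
        q_mpa=rec.q_mpa, q_lpa=noisy(rec.q_lpa), q_rpa=noisy(rec.q_rpa),
        condition=rec.condition, t_decay=rec.t_decay,
    )


@pytest.fixture(scope="session")
def multistart_calibration(virtual_subject, coarse_cfg):
    """Ten-start calibration of the noiseless baseline record."""
    from pulmo1d.calibration import calibrate

    return calibrate(
        virtual_subject.network,
        virtual_subject.baseline_record,
        cfg=coarse_cfg,
        n_starts=10,
        seed=123,
    )


@pytest.fixture(scope="session")
def cohort_results(coarse_cfg):
    """Five paired virtual subjects run through the full pipeline."""
    from pulmo1d.pipeline import RunConfig, run_subject
    from pulmo1d.stats import cohort_table
    from pulmo1d.synthetic import default_cohort

    cohort = default_cohort(
        n_subjects=5, seed=0, noise=0.0, solver_config=coarse_cfg
    )
    rc = RunConfig(solver=coarse_cfg, n_starts=2, seed=11)
    summaries = []
    for i, vs in enumerate(cohort):
        for rec in (vs.baseline_record, vs.cteph_record):
            s = run_subject(vs.network, rec, rc, subject=f"S{i + 1}")
            s.pop("timings", None)
            summaries.append(s)
    return cohort, cohort_table(summaries)
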