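"""Solver oracles: equilibrium, friction gradients, wave speed,
boundary behavior, conservation, and grid convergence."""

import numpy as np
import pytest

from pulmo1d import (
    ArterialNetwork,
    SolverConfig,
    TimeSeries,
    Vessel,
    WallModel,
    Windkessel3,
    WindkesselSet,
    solve_to_periodic,
    wave_speed,
)
from pulmo1d.solver import (
    ConvergenceError,
    cyclic_mass_error,
    junction_residuals,
)

from conftest import pulsatile_inflow, single_vessel_network

MU = 0.03
RHO = 1.03


def constant_inflow(q0, period=0.5, n=64):
    t = np.linspace(0, period, n, endpoint=False)
    return TimeSeries(times=t, values=np.full(n, q0), period=period)


class TestEquilibriumAndSteady:
    def test_zero_flow_rest_state_is_fixed_point(self, default_wall):
        """No forcing + outlet reference at P_dia leaves the rest state."""
        v = Vessel(id="MPA", role="MPA", length=4.0, inlet_radius=0.5,
                   outlet_radius=0.35)  # tapered on purpose
        net = ArterialNetwork(vessels={"MPA": v}, gamma=5.0)
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.1, r_dist=0.1, compliance=0.5, p_out=15.0)})
        state = solve_to_periodic(
            net, default_wall, wk, constant_inflow(0.0),
            SolverConfig(max_cycles=5, cycle_tolerance=1e-8),
        )
        a = state.area["MPA"]
        a0 = np.pi * np.asarray(v.r0(state.x["MPA"])) ** 2
        assert np.max(np.abs(a - a0[None, :]) / a0[None, :]) < 1e-12
        assert np.max(np.abs(state.flow["MPA"])) < 1e-12

    @pytest.mark.parametrize("gamma", [2.0, 5.0])
    def test_steady_friction_gradient(
        self, gamma, steady_single_vessel_states
    ):
        """Converged dP/dx equals -2*pi*mu*(gamma+2)*Q/A^2 (CGS)."""
        net, state = steady_single_vessel_states[gamma]
        p = state.pressure["MPA"][-1] * 1333.22
        a = state.area["MPA"][-1]
        x = state.x["MPA"]
        g_num = np.gradient(p, x)[2:-2]
        g_ana = -2 * np.pi * MU * (gamma + 2) * 10.0 / a[2:-2] ** 2
        assert np.max(np.abs(g_num - g_ana) / np.abs(g_ana)) < 0.01

    def test_steady_drop_matches_poiseuille(
        self, steady_single_vessel_states
    ):
        """End-to-end drop at gamma=2: 8*mu*Q*L/(pi*R^4) = 61.12 dyne/cm2."""
        _, state = steady_single_vessel_states[2.0]
        p = state.pressure["MPA"][-1] * 1333.22
        drop = p[0] - p[-1]
        expected = 8 * MU * 10.0 * 5.0 / (np.pi * 0.5**4)
        assert drop == pytest.approx(expected, rel=0.01)

    def test_constant_inflow_reaches_steady_state(
        self, steady_single_vessel_states
    ):
        _, state = steady_single_vessel_states[5.0]
        q = state.flow["MPA"]
        assert np.ptp(q) / np.max(np.abs(q)) < 1e-4


class TestInletBC:
    def test_prescribed_waveform_reproduced(self, pulsatile_three_vessel):
        net, wall, wks, q_in, state = pulsatile_three_vessel
        q_model = state.flow["MPA"][:, 0]
        q_data = np.asarray(q_in(state.t), dtype=float)
        assert np.max(np.abs(q_model - q_data)) < 1e-9 * np.max(q_data)

    def test_nonperiodic_waveform_rejected(self, default_wall):
        net = single_vessel_network(5.0)
        t = np.linspace(0, 0.5, 64, endpoint=False)
        ts = TimeSeries(times=t, values=np.linspace(0, 50, 64), period=0.5)
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.1, r_dist=0.1, compliance=0.5, p_out=10.0)})
        with pytest.raises(ValueError, match="periodic"):
            solve_to_periodic(net, default_wall, wk, ts)

    def test_time_shifted_inflow_shifts_solution(self, default_wall):
        """Shifting the inlet waveform by T/4 rotates the periodic
        solution by the same amount (periodicity of the converged state)."""
        net = single_vessel_network(5.0, length=4.0)
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.2, r_dist=0.3, compliance=0.4, p_out=10.0)})
        cfg = SolverConfig(cycle_tolerance=1e-10, max_cycles=100)
        q1 = pulsatile_inflow()
        shift = 0.125
        t = q1.times
        q2 = TimeSeries(times=t, values=np.asarray(q1(t - shift)),
                        period=q1.period)
        s1 = solve_to_periodic(net, default_wall, wk, q1, cfg)
        s2 = solve_to_periodic(net, default_wall, wk, q2, cfg)
        p1 = s1.series("MPA", "pressure")
        p2 = s2.series("MPA", "pressure")
        p1_shifted = np.interp(
            np.mod(s2.t - shift, s2.period), s1.t, p1
        )
        assert np.max(np.abs(p2 - p1_shifted)) < 0.02 * np.ptp(p1)


class TestOutletBC:
    def test_steady_windkessel_pressure(self, steady_single_vessel_states):
        """Constant flow drive: outlet P -> P_out + Q*(R_P + R_D)."""
        _, state = steady_single_vessel_states[5.0]
        p_out_expected = (15.0 - 10.0 * 0.04) + 10.0 * 0.04
        p_end = state.pressure["MPA"][-1, -1]
        # friction raises upstream pressure; at the outlet node the WK3
        # relation must hold exactly
        assert p_end == pytest.approx(p_out_expected, abs=0.01)

    def test_impulse_decays_with_rd_c_time_constant(self, default_wall):
        """After ejection stops, outlet pressure relaxes toward P_out
        with time constant ~ R_D*C (proximal resistor carries no flow)."""
        net = single_vessel_network(5.0, length=2.0)
        rd, c = 0.5, 0.4
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.05, r_dist=rd, compliance=c, p_out=15.0)})
        t = np.linspace(0, 1.0, 256, endpoint=False)
        qv = np.where(t < 0.08, 30 * np.sin(np.pi * t / 0.08), 0.0)
        q = TimeSeries(times=t, values=qv, period=1.0)
        state = solve_to_periodic(
            net, default_wall, wk, q,
            SolverConfig(cycle_tolerance=1e-10, max_cycles=120),
        )
        p = state.series("MPA", "pressure", 1.0) - 15.0
        tt = state.t
        # fit log-linear decay over mid-diastole
        sel = (tt > 0.3) & (tt < 0.8) & (p > 0)
        slope = np.polyfit(tt[sel], np.log(p[sel]), 1)[0]
        tau = -1.0 / slope
        assert tau == pytest.approx(rd * c, rel=0.15)


class TestJunctionsAndConservation:
    def test_junction_mass_balance_machine_precision(
        self, pulsatile_three_vessel
    ):
        net, _, _, _, state = pulsatile_three_vessel
        mass_res, _ = junction_residuals(net, state)
        assert mass_res < 1e-10

    def test_junction_pressure_continuity(self, pulsatile_three_vessel):
        net, _, _, _, state = pulsatile_three_vessel
        _, p_res = junction_residuals(net, state)
        assert p_res < 1e-10

    def test_symmetric_daughters_split_evenly(self, default_wall):
        vessels = {
            "MPA": Vessel(id="MPA", role="MPA", length=3.0,
                          inlet_radius=0.6, outlet_radius=0.6,
                          children=("LPA", "RPA")),
            "LPA": Vessel(id="LPA", role="LPA", length=2.0,
                          inlet_radius=0.45, outlet_radius=0.45,
                          parent="MPA"),
            "RPA": Vessel(id="RPA", role="RPA", length=2.0,
                          inlet_radius=0.45, outlet_radius=0.45,
                          parent="MPA"),
        }
        net = ArterialNetwork(vessels=vessels)
        wall = WallModel(stiffness=40.0, area_dia=np.pi * 0.36,
                         pressure_dia=12.0)
        q = pulsatile_inflow()
        wks = WindkesselSet({
            t: Windkessel3(r_prox=0.3, r_dist=0.3, compliance=0.5,
                           p_out=5.0) for t in ("LPA", "RPA")
        })
        state = solve_to_periodic(net, wall, wks, q, SolverConfig())
        q1 = state.flow["LPA"][:, 0]
        q2 = state.flow["RPA"][:, 0]
        assert np.max(np.abs(q1 - q2)) < 1e-9 * np.max(np.abs(q1) + 1e-12)

    def test_cyclic_mass_conservation(self, pulsatile_three_vessel):
        net, _, _, _, state = pulsatile_three_vessel
        assert cyclic_mass_error(net, state) < 1e-3

    def test_pressure_area_tube_law_consistency(
        self, pulsatile_three_vessel
    ):
        net, wall, _, _, state = pulsatile_three_vessel
        for vid in state.vessel_ids:
            a0 = np.pi * np.asarray(
                net.vessels[vid].r0(state.x[vid])) ** 2
            w = np.sqrt(state.area[vid] / a0[None, :])
            p_expected = (4.0 / 3.0) * wall.stiffness * (w - 1.0) + 12.0
            assert np.max(np.abs(state.pressure[vid] - p_expected)) < 1e-9

    def test_positivity(self, pulsatile_three_vessel):
        net, _, wks, _, state = pulsatile_three_vessel
        p_out = 5.0
        for vid in state.vessel_ids:
            assert np.all(state.area[vid] > 0)
            assert np.all(state.pressure[vid] > p_out)


class TestWavePropagation:
    def test_pulse_speed_matches_tube_law(self, default_wall):
        """Foot-to-foot transit over a long uniform vessel within 5%."""
        net = single_vessel_network(5.0, length=40.0)
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.26, r_dist=0.26, compliance=0.3, p_out=15.0)})
        t = np.linspace(0, 1.0, 256, endpoint=False)
        qv = np.where(t < 0.05, 2.0 * np.sin(np.pi * t / 0.05) ** 2, 0.0)
        q = TimeSeries(times=t, values=qv, period=1.0)
        state = solve_to_periodic(
            net, default_wall, wk, q,
            SolverConfig(max_cycles=100, cycle_tolerance=1e-9),
        )
        c_ana = wave_speed(default_wall, np.pi * 0.25, RHO)

        def foot_time(sig, thr):
            i = int(np.argmax(sig > thr))
            return np.interp(thr, [sig[i - 1], sig[i]],
                             [state.t[i - 1], state.t[i]])

        i1 = state.node_index("MPA", 5 / 40)
        i2 = state.node_index("MPA", 30 / 40)
        q1 = state.flow["MPA"][:, i1]
        q2 = state.flow["MPA"][:, i2]
        thr = 0.1 * q1.max()
        c_num = (state.x["MPA"][i2] - state.x["MPA"][i1]) / (
            foot_time(q2, thr) - foot_time(q1, thr)
        )
        assert c_num == pytest.approx(c_ana, rel=0.05)


class TestConvergenceControl:
    def test_converged_state_is_periodic_fixed_point(
        self, pulsatile_three_vessel, default_wall
    ):
        net, wall, wks, q, state = pulsatile_three_vessel
        # one extra solve warm-started from the converged state must stay
        # within the cycle tolerance immediately
        init = (
            np.concatenate([state.area[v][-1] for v in state.vessel_ids]),
            np.concatenate([state.flow[v][-1] for v in state.vessel_ids]),
        )
        again = solve_to_periodic(
            net, wall, wks, q,
            SolverConfig(cycle_tolerance=1e-8, max_cycles=3),
            initial_state=init,
        )
        assert again.cycles_used <= 3

    def test_nonconvergence_raises_with_metric(self, default_wall):
        net = single_vessel_network(5.0)
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.2, r_dist=0.3, compliance=0.4, p_out=10.0)})
        with pytest.raises(ConvergenceError) as exc:
            solve_to_periodic(
                net, default_wall, wk, pulsatile_inflow(),
                SolverConfig(max_cycles=2, cycle_tolerance=1e-14),
            )
        assert np.isfinite(exc.value.metric)

    def test_grid_convergence_systolic_pressure(self, default_wall):
        """Halving dx changes converged MPA systolic pressure < 0.5%."""
        wk = WindkesselSet({"MPA": Windkessel3(
            r_prox=0.2, r_dist=0.3, compliance=0.4, p_out=10.0)})
        q = pulsatile_inflow()
        p_sys = {}
        for dx in (0.25, 0.125):
            net = single_vessel_network(5.0)
            state = solve_to_periodic(
                net, default_wall, wk, q,
                SolverConfig(dx=dx, cycle_tolerance=1e-9),
            )
            p_sys[dx] = state.series("MPA", "pressure").max()
        assert abs(p_sys[0.125] - p_sys[0.25]) / p_sys[0.125] < 0.005
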