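"""Calibration: left-flow recomputation, cost structure, diagnostics,
and the monotone hemodynamic response to the scaling factors."""

import numpy as np
import pytest

from pulmo1d.calibration import (
    SubjectRecord,
    cost,
    fit_diagnostics,
    model_from_record,
    nominal_from_record,
    recompute_left_flow,
)
from pulmo1d.network import TimeSeries
from pulmo1d.windkessel import ScalingFactors, apply_scaling


def ts(values, period=0.5):
    values = np.asarray(values, dtype=float)
    t = np.linspace(0, period, values.size, endpoint=False)
    return TimeSeries(times=t, values=values, period=period)


class TestLeftFlowRecomputation:
    def test_half_split(self):
        t = np.linspace(0, 0.5, 32, endpoint=False)
        q_mpa = ts(40 + 20 * np.sin(2 * np.pi * t / 0.5))
        q_rpa = ts(q_mpa.values / 2)
        q_tilde = recompute_left_flow(q_mpa, q_rpa)
        assert np.allclose(q_tilde.values, q_mpa.values / 2)

    def test_pointwise_mass_balance(self):
        rng = np.random.default_rng(0)
        q_mpa = ts(40 + rng.normal(0, 5, 32))
        q_rpa = ts(20 + rng.normal(0, 3, 32))
        q_tilde = recompute_left_flow(q_mpa, q_rpa)
        assert np.allclose(q_tilde.values + q_rpa.values, q_mpa.values)

    def test_period_mismatch_rejected(self):
        q_mpa = ts(np.full(32, 40.0), period=0.5)
        q_rpa = ts(np.full(32, 20.0), period=0.6)
        with pytest.raises(ValueError, match="period"):
            recompute_left_flow(q_mpa, q_rpa)

    def test_generator_asymmetry_reproduced(self, virtual_subject):
        """The recomputed left share reflects the imposed obstruction."""
        br = virtual_subject.baseline_record
        cr = virtual_subject.cteph_record
        q_tilde = recompute_left_flow(cr.q_mpa, cr.q_rpa)
        share = q_tilde.mean / cr.q_mpa.mean
        share_base = br.q_lpa.mean / br.q_mpa.mean
        # the left-biased transform lowers the left-lung share
        assert share < share_base - 0.01
        # and the mean agrees with the directly simulated left flow
        assert q_tilde.mean == pytest.approx(cr.q_lpa.mean, rel=0.05)


class TestRecordValidation:
    def test_pressure_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord(
                p_sys=10.0, p_dia=12.0, p_pcw=5.0, a_sys=2.0, a_dia=1.0,
                q_mpa=ts(np.full(32, 40.0)),
                q_lpa=ts(np.full(32, 20.0)),
                q_rpa=ts(np.full(32, 20.0)),
            )

    def test_default_decay_window(self):
        rec = SubjectRecord(
            p_sys=20.0, p_dia=10.0, p_pcw=5.0, a_sys=2.0, a_dia=1.0,
            q_mpa=ts(np.full(32, 40.0)),
            q_lpa=ts(np.full(32, 20.0)),
            q_rpa=ts(np.full(32, 20.0)),
        )
        assert rec.t_decay == pytest.approx(0.3)
        assert rec.mpap == pytest.approx(40.0 / 3)


class TestCostStructure:
    def test_cost_near_zero_at_truth(self, virtual_subject, coarse_cfg):
        vs = virtual_subject
        net, wall = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net, vs.baseline_record)
        c = cost(vs.theta_truth, net, wall, wks, vs.baseline_record,
                 coarse_cfg)
        assert c < 1e-6

    def test_truth_is_local_minimum(self, virtual_subject, coarse_cfg):
        """S(theta_true*(1 +- 0.1)) > S(theta_true) on a perturbation
        grid around the truth (coarse 2-point probe per axis)."""
        vs = virtual_subject
        net, wall = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net, vs.baseline_record)
        c0 = cost(vs.theta_truth, net, wall, wks, vs.baseline_record,
                  coarse_cfg)
        tt = np.array(vs.theta_truth.as_tuple())
        for axis in range(3):
            for f in (0.9, 1.1):
                th = tt.copy()
                th[axis] *= f
                c = cost(ScalingFactors(*th), net, wall, wks,
                         vs.baseline_record, coarse_cfg)
                assert c > c0

    def test_monotone_pressure_response(self, virtual_subject, coarse_cfg):
        """Raising r_P or r_D raises mean MPA pressure; raising c lowers
        pulse pressure."""
        from pulmo1d.calibration import _forward, _model_observables

        vs = virtual_subject
        net, wall = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net, vs.baseline_record)

        def observe(theta):
            st = _forward(net, wall, wks, theta, vs.baseline_record,
                          coarse_cfg)
            ps, pdia, *_ = _model_observables(net, st,
                                              vs.baseline_record)
            return ps, pdia

        tt = vs.theta_truth.as_tuple()
        ps0, pd0 = observe(ScalingFactors(*tt))
        ps_rp, pd_rp = observe(ScalingFactors(tt[0] * 1.5, tt[1], tt[2]))
        ps_rd, pd_rd = observe(ScalingFactors(tt[0], tt[1] * 1.5, tt[2]))
        # compliance acts where the outlet capacitors still filter the
        # pulse: compare against a strongly reduced compliance
        ps_c, pd_c = observe(ScalingFactors(tt[0], tt[1], tt[2] * 0.3))
        assert ps_rp / 3 + 2 * pd_rp / 3 > ps0 / 3 + 2 * pd0 / 3
        assert ps_rd / 3 + 2 * pd_rd / 3 > ps0 / 3 + 2 * pd0 / 3
        assert ps_c - pd_c > ps0 - pd0

    def test_calibration_touches_windkessels_only(self, virtual_subject):
        """theta scaling changes neither the geometry nor the stiffness."""
        vs = virtual_subject
        net1, wall1 = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net1, vs.baseline_record)
        scaled = apply_scaling(wks, ScalingFactors(3.0, 0.2, 5.0))
        net2, wall2 = model_from_record(vs.network, vs.baseline_record)
        assert wall1 == wall2
        for vid in net1.vessels:
            assert net1.vessels[vid].inlet_radius == \
                net2.vessels[vid].inlet_radius
        assert scaled.r_prox_total == pytest.approx(3.0 * wks.r_prox_total)


class TestDiagnostics:
    def test_perfect_model_perfect_scores(self, virtual_subject,
                                          coarse_cfg):
        from pulmo1d.calibration import _forward

        vs = virtual_subject
        net, wall = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net, vs.baseline_record)
        state = _forward(net, wall, wks, vs.theta_truth,
                         vs.baseline_record, coarse_cfg)
        d = fit_diagnostics(net, state, vs.baseline_record)
        for k in ("rel_err_p_sys", "rel_err_p_dia", "rel_err_a_sys",
                  "rel_err_a_dia"):
            assert abs(d[k]) < 1e-3
        assert d["r2_q_lpa"] > 0.9999
        assert d["r2_q_rpa"] > 0.9999

    def test_undershoot_gives_negative_relative_error(
        self, virtual_subject, coarse_cfg
    ):
        from pulmo1d.calibration import _forward

        vs = virtual_subject
        net, wall = model_from_record(vs.network, vs.baseline_record)
        wks = nominal_from_record(net, vs.baseline_record)
        tt = vs.theta_truth.as_tuple()
        # halve the resistances: the model undershoots measured pressure
        state = _forward(net, wall, wks,
                         ScalingFactors(tt[0] / 2, tt[1] / 2, tt[2]),
                         vs.baseline_record, coarse_cfg)
        d = fit_diagnostics(net, state, vs.baseline_record)
        assert d["rel_err_p_sys"] < 0
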