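"""Velocity profiles, wall shear, TAWSS/OSI/phi oracles, gamma fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmo1d.shear import (
    RadialProfileSample,
    ShearSeries,
    fit_gamma,
    osi,
    phi_metric,
    powerlaw_profile,
    tawss,
    wall_shear_from_state,
)
from pulmo1d.synthetic import sample_radial_profile

MU = 0.03


def series(tau, period=1.0):
    tau = np.asarray(tau, dtype=float)
    t = np.linspace(0.0, period, tau.size)
    return ShearSeries(t=t, tau=tau, period=period)


def piecewise_series(vals_durations, n=4000):
    """Dense sampling of a piecewise-constant tau over one period."""
    total = sum(d for _, d in vals_durations)
    t = np.linspace(0, total, n)
    tau = np.empty(n)
    start = 0.0
    for v, d in vals_durations:
        tau[(t >= start) & (t <= start + d)] = v
        start += d
    return ShearSeries(t=t, tau=tau, period=total)


class TestPowerLawProfile:
    def test_no_slip_at_wall(self):
        assert powerlaw_profile(10.0, 0.5, 5.0, 0.5) == 0.0

    def test_centerline_poiseuille_limit(self):
        assert powerlaw_profile(10.0, 0.5, 2.0, 0.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("gamma", [2.0, 5.0, 7.0, 9.0])
    def test_disk_average_equals_mean_velocity(self, gamma):
        r = np.linspace(0, 0.5, 20001)
        u = powerlaw_profile(10.0, 0.5, gamma, r)
        u_avg = np.trapezoid(2 * np.pi * r * u, r) / (np.pi * 0.25)
        assert u_avg == pytest.approx(10.0, rel=1e-6)

    def test_out_of_range_radius_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_profile(10.0, 0.5, 5.0, 0.6)


class TestWallShear:
    def test_poiseuille_oracle(self, steady_single_vessel_states):
        """gamma=2 steady: |tau| = 4*mu*Q/(pi*R^3) = 3.056 dyne/cm^2."""
        net, state = steady_single_vessel_states[2.0]
        s = wall_shear_from_state(state, MU, 2.0, "MPA")
        mid = state.node_index("MPA", 0.5)
        r_actual = np.sqrt(state.area["MPA"][-1, mid] / np.pi)
        expected = 4 * MU * 10.0 / (np.pi * r_actual**3)
        assert abs(s.tau[-1, mid]) == pytest.approx(expected, rel=1e-6)
        assert abs(s.tau[-1, mid]) == pytest.approx(3.056, rel=0.05)

    def test_zero_flow_zero_shear(self):
        class FakeState:
            vessel_ids = ["v"]
            area = {"v": np.full((4, 3), 0.8)}
            flow = {"v": np.zeros((4, 3))}
            t = np.linspace(0, 1, 4)
            period = 1.0

        s = wall_shear_from_state(FakeState(), MU, 5.0, "v")
        assert np.all(s.tau == 0.0)

    def test_gamma_ratio_at_fixed_flow(self, steady_single_vessel_states):
        net, state = steady_single_vessel_states[2.0]
        s2 = wall_shear_from_state(state, MU, 2.0, "MPA")
        s5 = wall_shear_from_state(state, MU, 5.0, "MPA")
        ratio = s5.tau[-1, 1:-1] / s2.tau[-1, 1:-1]
        assert np.allclose(ratio, 7.0 / 4.0, rtol=1e-12)


class TestTawssOsi:
    def test_constant_shear(self):
        assert tawss(series(np.full(200, 3.0))) == pytest.approx(3.0)

    def test_sinusoid_two_over_pi(self):
        t = np.linspace(0, 1, 20001)
        s = ShearSeries(t=t, tau=np.sin(2 * np.pi * t), period=1.0)
        assert tawss(s) == pytest.approx(2 / np.pi, rel=1e-5)
        assert osi(s) == pytest.approx(0.5, abs=1e-5)

    def test_piecewise_hand_case(self):
        """tau = +2 for T/2, -1 for T/2: TAWSS 1.5, OSI 1/3."""
        s = piecewise_series([(2.0, 0.5), (-1.0, 0.5)], n=20000)
        assert tawss(s) == pytest.approx(1.5, rel=1e-3)
        assert osi(s) == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_unidirectional_osi_zero(self):
        s = series(np.abs(np.sin(np.linspace(0, 2 * np.pi, 400))) + 0.1)
        assert osi(s) == pytest.approx(0.0, abs=1e-12)

    def test_zero_shear_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            assert osi(series(np.zeros(100))) == 0.0

    @given(
        amp=st.floats(0.1, 50.0),
        offset=st.floats(-50.0, 50.0),
        phase=st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=100, deadline=None)
    def test_osi_bounds_and_sign_invariance(self, amp, offset, phase):
        t = np.linspace(0, 1, 801)
        tau = offset + amp * np.sin(2 * np.pi * t + phase)
        s_pos = ShearSeries(t=t, tau=tau, period=1.0)
        s_neg = ShearSeries(t=t, tau=-tau, period=1.0)
        v = osi(s_pos)
        assert 0.0 <= v <= 0.5
        assert osi(s_neg) == pytest.approx(v, abs=1e-12)
        assert tawss(s_neg) == pytest.approx(tawss(s_pos), abs=1e-12)
        assert tawss(s_pos) >= 0.0


class TestPhi:
    def table(self, tawss_vals, osi_vals, roles=None):
        n = len(tawss_vals)
        roles = roles or ["intralobar"] * n
        return pd.DataFrame({
            "vessel": [f"v{i}" for i in range(n)],
            "role": roles,
            "length_cm": np.linspace(1.0, 2.0, n),
            "tawss": tawss_vals,
            "osi": osi_vals,
        })

    def test_none_qualify(self):
        t = self.table([10.0] * 4, [0.0] * 4)
        assert phi_metric(t) == 0.0

    def test_all_qualify(self):
        t = self.table([1.0] * 4, [0.2] * 4)
        assert phi_metric(t) == 100.0

    def test_hand_count(self):
        t = self.table([1.0, 10.0, 6.0, 2.0], [0.2, 0.2, 0.01, 0.01])
        assert phi_metric(t) == pytest.approx(25.0)

    def test_scope_excludes_extralobar(self):
        t = self.table([1.0, 1.0], [0.2, 0.2], roles=["MPA", "intralobar"])
        assert phi_metric(t, scope="intralobar") == 100.0
        assert phi_metric(t, scope="all") == 100.0
        with pytest.raises(ValueError):
            phi_metric(t.iloc[:1], scope="intralobar")

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(0)
        t = self.table(rng.uniform(0, 12, 30), rng.uniform(0, 0.3, 30))
        phis = [phi_metric(t, tawss_cutoff=c) for c in (2.0, 5.0, 9.0)]
        assert phis == sorted(phis)
        phis2 = [phi_metric(t, osi_cutoff=c) for c in (0.01, 0.05, 0.2)]
        assert phis2 == sorted(phis2, reverse=True)


class TestGammaFit:
    @pytest.mark.parametrize("gamma_true", [2.0, 5.0])
    def test_noiseless_self_consistency(self, gamma_true):
        sample = sample_radial_profile(gamma_true, 30.0, 0.8, noise=0.0)
        best, sse = fit_gamma(sample)
        assert best == gamma_true
        assert sse[gamma_true] == pytest.approx(0.0, abs=1e-20)

    def test_noise_raises_sse_at_truth(self):
        s0 = sample_radial_profile(5.0, 30.0, 0.8, noise=0.0, seed=1)
        s1 = sample_radial_profile(5.0, 30.0, 0.8, noise=0.10, seed=1)
        assert fit_gamma(s1)[1][5.0] > fit_gamma(s0)[1][5.0]

    def test_seeded_reproducibility(self):
        a = sample_radial_profile(5.0, 30.0, 0.8, noise=0.05, seed=7)
        b = sample_radial_profile(5.0, 30.0, 0.8, noise=0.05, seed=7)
        assert np.array_equal(a.velocities, b.velocities)

    def test_nonpositive_flow_rejected(self):
        sample = RadialProfileSample(
            radii=np.linspace(0, 0.5, 8),
            velocities=np.full(8, -1.0),
            lumen_radius=0.5,
        )
        with pytest.raises(ValueError):
            fit_gamma(sample)
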