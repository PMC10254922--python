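"""Unit and property tests for the kinetic forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from shgkin import (
    GAS_CONSTANT,
    ArrheniusLaw,
    BiExpParams,
    KineticParams,
    biexp_field,
    field_from_trajectory,
    rate_at_temperature,
    solve_linear_chain,
)
from shgkin.synthetic_data import get_preset, mechanistic_field


def ode_oracle(params, times, initial):
    """Independent stiff numerical integration of the four-state chain."""

    def rhs(_, n):
        sol, up, flip, inner = n
        return [
            -params.k_ads * sol,
            params.k_ads * sol - params.k_flip * up,
            params.k_flip * up - params.k_trans * flip + params.k_back * inner,
            params.k_trans * flip - params.k_back * inner,
        ]

    res = solve_ivp(
        rhs, (times[0], times[-1]), initial, t_eval=times, method="LSODA",
        rtol=1e-11, atol=1e-12,
    )
    assert res.success
    return res.y.T


class TestSolveLinearChain:
    def test_single_step_decay(self):
        """With only adsorption active, solution drains exponentially into n_up."""
        p = KineticParams(k_ads=0.3, k_flip=0.0, k_trans=0.0)
        t = np.linspace(0.0, 20.0, 50)
        traj = solve_linear_chain(p, t)
        np.testing.assert_allclose(traj.n_solution, np.exp(-0.3 * t), atol=1e-12)
        np.testing.assert_allclose(traj.n_up, 1.0 - np.exp(-0.3 * t), atol=1e-12)

    def test_all_rates_zero_is_identity(self):
        p = KineticParams(k_ads=0.0, k_flip=0.0, k_trans=0.0)
        init = np.array([0.2, 0.3, 0.4, 0.1])
        traj = solve_linear_chain(p, np.linspace(0, 100, 11), initial=init)
        for got, want in zip(
            (traj.n_solution, traj.n_up, traj.n_flip, traj.n_in), init
        ):
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_stiff_integrator(self):
        p = KineticParams(k_ads=1.0, k_flip=0.05, k_trans=0.002)
        t = np.linspace(0.0, 3000.0, 301)
        traj = solve_linear_chain(p, t)
        expected = ode_oracle(p, t, [1.0, 0.0, 0.0, 0.0])
        got = np.column_stack((traj.n_solution, traj.n_up, traj.n_flip, traj.n_in))
        assert np.max(np.abs(got - expected)) < 1e-7

    def test_degenerate_rates_use_limiting_form(self):
        """Equal eigenvalues (k_ads == k_flip) must not blow up the closed form."""
        p = KineticParams(k_ads=0.05, k_flip=0.05, k_trans=0.002, k_back=0.001)
        t = np.linspace(0.0, 2000.0, 101)
        traj = solve_linear_chain(p, t)
        expected = ode_oracle(p, t, [1.0, 0.0, 0.0, 0.0])
        got = np.column_stack((traj.n_solution, traj.n_up, traj.n_flip, traj.n_in))
        assert np.max(np.abs(got - expected)) < 1e-7

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_flip"):
            KineticParams(k_ads=1.0, k_flip=-0.1, k_trans=0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        ka=st.floats(1e-4, 10.0),
        kf=st.floats(1e-4, 1.0),
        kt=st.floats(1e-5, 0.1),
        kb=st.floats(0.0, 0.1),
    )
    def test_mass_conservation(self, ka, kf, kt, kb):
        """Total population is conserved to 1e-9 relative at every time point."""
        p = KineticParams(k_ads=ka, k_flip=kf, k_trans=kt, k_back=kb, n_total=2.5)
        t = np.linspace(0.0, 5000.0, 200)
        traj = solve_linear_chain(p, t)
        np.testing.assert_allclose(traj.total, 2.5, rtol=1e-9)
        for arr in (traj.n_solution, traj.n_up, traj.n_flip, traj.n_in):
            assert np.all(arr >= 0)


class TestFieldFromTrajectory:
    def test_empty_surface_gives_zero_field(self):
        p = KineticParams(k_ads=0.0, k_flip=0.0, k_trans=0.0)
        traj = solve_linear_chain(p, np.linspace(0, 10, 30))
        np.testing.assert_array_equal(field_from_trajectory(traj), 0.0)

    def test_perfect_two_side_cancellation(self):
        """Equal upright and inner populations with w_in = -1 null the field."""
        p = KineticParams(k_ads=0.0, k_flip=0.0, k_trans=0.0)
        init = np.array([0.0, 0.4, 0.0, 0.4])
        traj = solve_linear_chain(p, np.linspace(0, 10, 30), initial=init)
        e = field_from_trajectory(traj, weights=(1.0, -0.6, -1.0))
        np.testing.assert_array_equal(e, 0.0)

    def test_late_log_slope_is_slow_eigenvalue(self):
        """The mechanistic decay tail follows the smallest nonzero eigenvalue."""
        pre = get_preset("dopg_guv")
        t = np.arange(0.0, 3000.0, 1.0)
        e = mechanistic_field(pre, 306.15, t)
        assert np.argmax(e) < 60  # rises within seconds
        k = rate_at_temperature(pre.law, 306.15)
        lam_slow = k * (1.0 + pre.kinetic.k_back / pre.kinetic.k_trans)
        mask = (t > 800) & (e > 0)
        slope = -np.polyfit(t[mask], np.log(e[mask]), 1)[0]
        assert abs(slope - lam_slow) / lam_slow < 0.02


class TestBiexpField:
    def test_zero_amplitudes_give_plateau(self):
        p = BiExpParams(A0=3.0, B1=0.0, tau1=10.0, B2=0.0, tau2=100.0)
        np.testing.assert_array_equal(biexp_field(p, np.arange(5.0)), 3.0)

    def test_value_at_origin_is_total_amplitude(self):
        p = BiExpParams(A0=1.0, B1=2.0, tau1=30.0, B2=1.5, tau2=600.0, t0=12.0)
        assert biexp_field(p, np.array([12.0]))[0] == pytest.approx(4.5, abs=1e-15)

    def test_direct_evaluation(self, biexp_params):
        got = biexp_field(biexp_params, np.array([600.0]))[0]
        want = 1.0 + 2.0 * np.exp(-20.0) + 1.5 * np.exp(-1.0)  # ~1.55181916
        assert got == pytest.approx(want, rel=1e-12)

    def test_rejects_time_before_origin(self, biexp_params):
        with pytest.raises(ValueError, match="before t0"):
            biexp_field(
                BiExpParams(A0=1, B1=1, tau1=1.0, B2=1, tau2=2.0, t0=5.0),
                np.array([4.0, 6.0]),
            )

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau1"):
            BiExpParams(A0=1.0, B1=1.0, tau1=600.0, B2=1.0, tau2=30.0)


class TestRateAtTemperature:
    def test_zero_barrier_is_temperature_independent(self):
        law = ArrheniusLaw(Ea=0.0, lnA=-2.0)
        assert rate_at_temperature(law, 294.0) == rate_at_temperature(law, 350.0)

    def test_rate_ratio_closed_form(self):
        law = ArrheniusLaw.from_rate_at(68.0, 294.0, 1e-3)
        ratio = rate_at_temperature(law, 318.0) / rate_at_temperature(law, 294.0)
        want = np.exp(68000.0 / GAS_CONSTANT * (1 / 294.0 - 1 / 318.0))  # ~8.14
        assert ratio == pytest.approx(want, rel=1e-12)
        assert 8.0 < ratio < 8.3

    def test_doubling_ea_doubles_arrhenius_slope(self):
        T = np.array([290.0, 310.0])
        for lnA in (-1.0, 5.0):
            k1 = rate_at_temperature(ArrheniusLaw(Ea=40.0, lnA=lnA), T)
            k2 = rate_at_temperature(ArrheniusLaw(Ea=80.0, lnA=lnA), T)
            s1 = np.diff(np.log(k1)) / np.diff(1.0 / T)
            s2 = np.diff(np.log(k2)) / np.diff(1.0 / T)
            assert s2[0] == pytest.approx(2.0 * s1[0], rel=1e-12)

    def test_monotone_in_temperature(self):
        law = ArrheniusLaw.from_rate_at(68.0, 306.15, 1e-3)
        k = rate_at_temperature(law, np.linspace(280.0, 330.0, 20))
        assert np.all(np.diff(k) > 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            rate_at_temperature(ArrheniusLaw(Ea=50.0, lnA=0.0), -1.0)
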