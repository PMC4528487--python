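import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ctlsim import (ODEParams, cstar_extended, cstar_simple,
                    expected_search_time, simple_mass_action,
                    solve_extended_model)


class TestExpectedSearchTime:
    @pytest.mark.parametrize("k,I,expected", [
        (0.7, 0.01, 1000 / 7),   # ~143 min; quoted as ~140
        (0.7, 0.02, 500 / 7),    # ~71 min; quoted as 70
        (0.7, 0.04, 250 / 7),    # ~36 min; quoted as 35
        (0.02, 1.0, 50.0),       # packed cluster at the slow rate
    ])
    def test_reciprocal_rule(self, k, I, expected):
        assert expected_search_time(k, I) == pytest.approx(expected)

    def test_zero_infected_fraction_signalled(self):
        with pytest.raises(ValueError, match="diverges"):
            expected_search_time(0.7, 0.0)
        with pytest.raises(ValueError):
            expected_search_time(0.0, 0.5)


class TestSimpleMassAction:
    def test_balance_point_is_stationary(self):
        p = ODEParams(r=1.0, k=0.022, C0=cstar_simple(1.0, 0.022), T0=0.01)
        t = np.linspace(0, 10 * 1440, 50)
        np.testing.assert_allclose(simple_mass_action(p, t), 0.01)

    def test_doubling_time_without_ctl(self):
        p = ODEParams(r=1.0, k=0.022, C0=0.0, T0=0.01)
        t_double = np.log(2) / 1.0 * 24  # hours
        assert simple_mass_action(p, t_double * 60) == pytest.approx(0.02)
        assert t_double == pytest.approx(16.6, rel=0.01)

    def test_agrees_with_numerical_integrator(self):
        """Independent route: scipy's IVP solver on dI/dt = (r - kC)I."""
        p = ODEParams(r=1.0, k=0.7, C0=0.002, T0=0.01)
        t = np.linspace(0, 3 * 1440, 20)
        sol = solve_ivp(lambda _, y: (p.r_per_min - p.k * p.C0) * y,
                        (0, t[-1]), [p.T0], t_eval=t, rtol=1e-11, atol=1e-30)
        np.testing.assert_allclose(simple_mass_action(p, t), sol.y[0],
                                   rtol=1e-8)


class TestCstarSimple:
    def test_slow_rate_value(self):
        assert cstar_simple(1.0, 0.022) == pytest.approx(0.0316, rel=2e-3)

    def test_zero_growth(self):
        assert cstar_simple(0.0, 0.022) == 0.0

    def test_inverse_proportionality_in_k(self):
        assert cstar_simple(1.0, 0.044) == pytest.approx(
            cstar_simple(1.0, 0.022) / 2)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            cstar_simple(1.0, 0.0)


class TestExtendedModel:
    def test_ctl_conservation(self):
        p = ODEParams(r=1.0, k=0.7, h=30.0, C0=0.01, T0=0.01)
        traj = solve_extended_model(p, 5 * 1440.0, sample_every=10)
        np.testing.assert_allclose(traj.C_free + traj.conjugates, p.C0,
                                   atol=1e-6 * p.C0)

    def test_vanishing_handling_time_matches_closed_form(self):
        p = ODEParams(r=1.0, k=0.7, h=1e-3, C0=0.002, T0=0.01)
        traj = solve_extended_model(p, 5 * 1440.0, dtau=1e-3,
                                    sample_every=100_000)
        expected = simple_mass_action(p, traj.t)
        np.testing.assert_allclose(traj.T, expected, rtol=5e-3)

    def test_excess_ctl_matches_closed_form(self):
        """C0 >> T0: conjugates never deplete the CTL pool appreciably."""
        p = ODEParams(r=1.0, k=0.7, h=30.0, C0=0.5, T0=1e-4)
        traj = solve_extended_model(p, 5 * 1440.0, sample_every=10)
        expected = simple_mass_action(p, traj.t)
        m = expected > 1e-100  # avoid comparing numerically dead tails
        np.testing.assert_allclose(traj.T[m], expected[m], rtol=0.01)

    def test_nonnegative_and_grid_convergence(self):
        """At the default age resolution, halving the grid moves the
        trajectory by < 0.1% even with ~40% of the CTL pool sequestered."""
        p = ODEParams(r=1.0, k=0.7, h=30.0, C0=0.003, T0=0.02)
        coarse = solve_extended_model(p, 2 * 1440.0, sample_every=600)
        fine = solve_extended_model(p, 2 * 1440.0, dtau=0.05,
                                    sample_every=1200)
        assert np.all(coarse.T >= 0) and np.all(coarse.conjugates >= -1e-15)
        np.testing.assert_allclose(coarse.T, fine.T, rtol=1e-3)

    def test_rejects_dtau_not_dividing_h(self):
        p = ODEParams(r=1.0, k=0.7, h=30.0, C0=0.003, T0=0.02)
        with pytest.raises(ValueError, match="divide"):
            solve_extended_model(p, 1440.0, dtau=7.0)


class TestCstarExtended:
    def test_reduces_to_mass_action_at_zero_handling(self):
        p = ODEParams(r=1.0, k=0.7, h=0.0, T0=0.01)
        assert cstar_extended(p) == cstar_simple(1.0, 0.7)

    def test_exceeds_mass_action_and_matches_qss(self):
        """Quasi-steady-state oracle: per-CTL kill rate kT/(1 + kTh) gives
        C* ~ r (1 + k T0 h)/k for slowly varying T."""
        p = ODEParams(r=1.0, k=0.7, h=30.0, T0=0.01)
        got = cstar_extended(p)
        base = cstar_simple(1.0, 0.7)
        qss = base * (1 + 0.7 * 0.01 * 30.0)
        assert got > base
        assert got == pytest.approx(qss, rel=0.15)

    def test_monotone_in_h_and_t0(self):
        vals_h = [cstar_extended(ODEParams(r=1.0, k=0.7, h=h, T0=0.01))
                  for h in (0.0, 10.0, 30.0, 60.0)]
        assert all(a <= b + 1e-12 for a, b in zip(vals_h, vals_h[1:]))
        vals_t = [cstar_extended(ODEParams(r=1.0, k=0.7, h=30.0, T0=t0))
                  for t0 in (0.005, 0.01, 0.04)]
        assert all(a <= b + 1e-12 for a, b in zip(vals_t, vals_t[1:]))
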