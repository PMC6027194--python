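"""Kinetic primitives: Arrhenius laws, rate evaluation, Euler stepping."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fermkin import (
    DEFAULT_THERMO,
    FermentationState,
    KineticParameters,
    TemperatureSchedule,
    arrhenius_rate,
    current_rates,
    kinetic_params_at,
    simulate,
    step,
)

# High-precision closed-form evaluations of A*exp(-E/(R*T)) with the
# default thermodynamic constants, frozen as independent oracles.
ARRHENIUS_ORACLE = {
    ("A1", 303.15): 0.3746193799513752,
    ("A1", 313.15): 0.7462756351000551,
    ("A2", 313.15): 0.03311956236752236,
    ("A3", 313.15): 2.280958099631009,
    ("A4", 313.15): 0.0018444059399437085,
}


class TestArrhenius:
    def test_zero_activation_energy_returns_frequency_factor(self):
        assert arrhenius_rate(3.7, 0.0, 300.0) == pytest.approx(3.7)

    @pytest.mark.parametrize(("key", "expected"), ARRHENIUS_ORACLE.items())
    def test_matches_closed_form_oracle(self, key, expected):
        name, T = key
        A = getattr(DEFAULT_THERMO, name)
        E = getattr(DEFAULT_THERMO, "E" + name[1])
        assert arrhenius_rate(A, E, T) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(250, 350), st.floats(250, 350))
    def test_monotone_in_temperature(self, T1, T2):
        if T1 == T2:
            return
        lo, hi = sorted([T1, T2])
        assert arrhenius_rate(1e8, 1e4, lo) < arrhenius_rate(1e8, 1e4, hi)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_rate(1.0, 1.0, 0.0)


class TestKineticParamsAt:
    def test_40C_growth_rate(self):
        params = kinetic_params_at(40.0)
        assert params.mu0 == pytest.approx(0.7462756351000551, rel=1e-12)

    def test_all_rates_increase_with_temperature(self):
        cold, hot = kinetic_params_at(20.0), kinetic_params_at(40.0)
        for name in ("mu0", "beta0", "k_prime", "k_dprime"):
            assert getattr(hot, name) > getattr(cold, name)

    def test_alpha_n_passed_through(self):
        params = kinetic_params_at(30.0, alpha=3.5, n=1.2)
        assert (params.alpha, params.n) == (3.5, 1.2)

    @pytest.mark.parametrize("temp", [-40.0, 120.0])
    def test_guard_range(self, temp):
        with pytest.raises(ValueError, match="range"):
            kinetic_params_at(temp)


class TestRatesAndStep:
    PARAMS = KineticParameters(
        mu0=0.5, beta0=1.0, k_prime=0.01, k_dprime=0.005, alpha=2.0, n=1.0
    )

    def test_no_history_gives_initial_rates(self):
        state = FermentationState(x=1.0)
        mu, beta, v = current_rates(state, self.PARAMS)
        assert (mu, beta) == (0.5, 1.0)
        assert v == pytest.approx(2.0 * 0.5 + 1.0)

    def test_single_euler_step_hand_computed(self):
        state = FermentationState(t=0.0, x=1.0, p=0.0)
        new = step(state, self.PARAMS, dt=0.1)
        assert new.x == pytest.approx(1.05)
        assert new.p == pytest.approx(0.2)
        assert new.t == pytest.approx(0.1)

    def test_zero_deactivation_gives_geometric_growth(self):
        params = KineticParameters(
            mu0=0.5, beta0=1.0, k_prime=0.0, k_dprime=0.0, alpha=2.0, n=1.0
        )
        state = FermentationState(x=1.0, p=0.0)
        for _ in range(50):
            state = step(state, params, dt=0.1)
        assert state.x == pytest.approx(1.05**50, rel=1e-12)
        mu, beta, _ = current_rates(state, params)
        assert (mu, beta) == (0.5, 1.0)

    @given(
        st.floats(0.01, 1.0),
        st.floats(0.0, 50.0),
        st.floats(0.001, 0.5),
        st.sampled_from(["current", "historical"]),
    )
    def test_step_never_decreases_state(self, x, p, dt, inhibition):
        state = FermentationState(x=x, p=p, s_p=p * 0.5)
        new = step(state, self.PARAMS, dt, inhibition=inhibition)
        assert new.x >= state.x
        assert new.p >= state.p
        assert new.s_p >= state.s_p

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step(FermentationState(x=1.0), self.PARAMS, dt=0.0)


class TestSimulate:
    def test_zero_horizon_is_single_initial_record(self):
        traj = simulate(TemperatureSchedule.constant(30.0), 0.0, x0=1.0)
        assert len(traj) == 1
        assert traj.cellmass_gL[0] == 1.0
        assert traj.ethanol_gL[0] == 0.0

    def test_noninteger_step_ratio_rounds_up_with_warning(self):
        with pytest.warns(UserWarning, match="integer multiple"):
            traj = simulate(
                TemperatureSchedule.constant(30.0), 1.05, dt=0.1, x0=0.5
            )
        assert len(traj) == 12  # 11 steps + initial record
        assert traj.final_time == pytest.approx(1.1)

    @pytest.mark.parametrize("inhibition", ["current", "historical"])
    def test_simulate_equals_iterated_step(self, inhibition):
        sched = TemperatureSchedule.exponential(40.0, 20.0, 2.0)
        traj = simulate(
            sched, 2.0, x0=0.5, alpha=2.2, n=1.0, dt=0.1, inhibition=inhibition
        )
        state = FermentationState(x=0.5, p=0.0)
        for i in range(20):
            params = kinetic_params_at(sched(i * 0.1), alpha=2.2, n=1.0)
            state = step(state, params, 0.1, inhibition=inhibition)
        assert state.x == pytest.approx(traj.final_cellmass, rel=1e-12)
        assert state.p == pytest.approx(traj.final_ethanol, rel=1e-12)

    @pytest.mark.parametrize("inhibition", ["current", "historical"])
    def test_monotone_trajectory_invariants(self, inhibition):
        sched = TemperatureSchedule.exponential(40.0, 20.0, 30.0)
        traj = simulate(sched, 30.0, x0=0.2, dt=0.05, inhibition=inhibition)
        traj.validate()  # uniform grid, monotone x/p, positive rates

    def test_rates_nonincreasing_at_constant_temperature(self):
        traj = simulate(TemperatureSchedule.constant(35.0), 40.0, dt=0.05)
        assert np.all(np.diff(traj.mu_per_h) <= 1e-15)
        assert np.all(np.diff(traj.beta_per_h) <= 1e-15)

    def test_inhibition_exponent_matches_product_form(self):
        """exp(-k'*sum(p_i^n dt)) must equal prod(exp(-k' p_i^n dt))."""
        sched = TemperatureSchedule.constant(33.0)
        dt, n_steps = 0.1, 300
        traj = simulate(sched, dt * n_steps, x0=0.3, dt=dt)
        params = kinetic_params_at(33.0)
        prod_mu = np.cumprod(
            np.exp(-params.k_prime * traj.ethanol_gL[:-1] ** 1.0 * dt)
        )
        np.testing.assert_allclose(
            traj.mu_per_h[1:], params.mu0 * prod_mu, rtol=1e-9
        )

    def test_conventions_agree_at_constant_temperature(self):
        sched = TemperatureSchedule.constant(25.0)
        a = simulate(sched, 20.0, dt=0.05, inhibition="current")
        b = simulate(sched, 20.0, dt=0.05, inhibition="historical")
        np.testing.assert_allclose(a.ethanol_gL, b.ethanol_gL, rtol=1e-12)

    def test_zero_inhibition_matches_closed_form(self):
        """With k'=k''=0 the continuous model is exactly exponential:
        x = x0 e^{mu0 t}, p = p0 + (alpha mu0 + beta0)/mu0 x0 (e^{mu0 t}-1)."""
        thermo = DEFAULT_THERMO.__class__(
            A1=DEFAULT_THERMO.A1, E1=DEFAULT_THERMO.E1,
            A2=1e-300, E2=0.0, A3=DEFAULT_THERMO.A3, E3=DEFAULT_THERMO.E3,
            A4=1e-300, E4=0.0,
        )
        params = kinetic_params_at(30.0, thermo)
        x0, alpha, t_end = 0.1, 2.2, 10.0
        traj = simulate(
            TemperatureSchedule.constant(30.0), t_end,
            x0=x0, alpha=alpha, thermo=thermo, dt=0.001,
        )
        x_exact = x0 * math.exp(params.mu0 * t_end)
        p_exact = (
            (alpha * params.mu0 + params.beta0) / params.mu0
            * x0 * (math.exp(params.mu0 * t_end) - 1.0)
        )
        assert traj.final_cellmass == pytest.approx(x_exact, rel=2e-3)
        assert traj.final_ethanol == pytest.approx(p_exact, rel=2e-3)


def ode_reference(temp_C, x0, p0, alpha, n, t_end):
    """High-accuracy solution of the equivalent ODE system at constant T:
    dx/dt = mu x, dp/dt = (alpha mu + beta) x, dmu/dt = -k' p^n mu,
    dbeta/dt = -k'' p^n beta."""
    params = kinetic_params_at(temp_C, alpha=alpha, n=n)

    def rhs(_, y):
        x, p, mu, beta = y
        return [
            mu * x,
            (alpha * mu + beta) * x,
            -params.k_prime * p**n * mu,
            -params.k_dprime * p**n * beta,
        ]

    sol = solve_ivp(
        rhs, (0.0, t_end), [x0, p0, params.mu0, params.beta0],
        method="LSODA", rtol=1e-11, atol=1e-12,
    )
    return sol.y[0, -1], sol.y[1, -1]


class TestEulerConvergence:
    def test_first_order_convergence_to_ode_limit(self):
        x_ref, p_ref = ode_reference(30.0, 0.1, 0.0, 2.2, 1.0, 20.0)
        errors = []
        for dt in (0.2, 0.1, 0.05, 0.025):
            traj = simulate(
                TemperatureSchedule.constant(30.0), 20.0, x0=0.1, dt=dt
            )
            errors.append(abs(traj.final_ethanol - p_ref))
        orders = [
            math.log2(errors[i] / errors[i + 1]) for i in range(len(errors) - 1)
        ]
        assert errors[-1] < errors[0] / 4
        assert orders[-1] == pytest.approx(1.0, abs=0.25)
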