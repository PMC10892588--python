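"""Closed-form state solutions against ODE oracles, limits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from larvenet import (
    ModelParameters,
    TimeGrid,
    Trajectory,
    evaluate_closed_forms,
    gls_ingestion,
    herbivory,
    integrate_model,
    itc_concentration,
    net_energy,
    net_energy_rate,
)
from conftest import draw_parameter_sets

B = 14.58


class TestHerbivory:
    @pytest.mark.parametrize(
        "t,theta,expected",
        [
            (0.0, 0.3, 0.0),           # no feeding before hatching
            (2.0, 0.3, 0.6),           # theta*t^2/2 by hand
            (20.0, 0.3, 0.0),          # herbivory ceases beyond development
            (B, 0.3, 0.5 * 0.3 * B**2),  # boundary t=b still feeds
        ],
    )
    def test_piecewise_quadratic(self, t, theta, expected):
        assert herbivory(t, theta, B) == pytest.approx(expected, abs=1e-12)

    def test_matches_ode_of_linear_rate(self):
        sol = solve_ivp(lambda t, y: [0.3 * t], (0, 10), [0.0], rtol=1e-10, atol=1e-12)
        assert herbivory(10.0, 0.3, B) == pytest.approx(sol.y[0, -1], abs=1e-8)

    def test_strictly_increasing_on_development_window(self):
        t = np.linspace(0, B, 500)
        h = herbivory(t, 0.3, B)
        assert np.all(np.diff(h) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            herbivory(-1.0, 0.3, B)


class TestGlsIngestion:
    @pytest.mark.parametrize(
        "t,alpha,expected", [(0.0, 0.4, 0.0), (3.0, 0.4, 1.8)]
    )
    def test_quadratic(self, t, alpha, expected):
        assert gls_ingestion(t, alpha, B) == pytest.approx(expected, abs=1e-12)

    def test_proportional_to_herbivory(self):
        """theta*G(t) == alpha*H(t) exactly: ingestion tracks consumption."""
        t = np.linspace(0, 2 * B, 400)
        theta, alpha = 0.3, 0.4
        np.testing.assert_allclose(
            theta * gls_ingestion(t, alpha, B), alpha * herbivory(t, theta, B), rtol=1e-15
        )

    def test_equals_herbivory_when_rates_match(self):
        t = np.linspace(0, B, 100)
        np.testing.assert_array_equal(gls_ingestion(t, 0.3, B), herbivory(t, 0.3, B))


class TestItcConcentration:
    def test_zero_at_origin(self):
        assert itc_concentration(0.0, 0.2, 0.8) == 0.0

    def test_matches_high_order_ode_integration(self):
        """Closed form vs dI/dt = beta*t - gamma*I from I(0)=0."""
        sol = solve_ivp(
            lambda t, y: [0.2 * t - 0.8 * y[0]], (0, 5), [0.0],
            method="DOP853", rtol=1e-12, atol=1e-14,
        )
        assert itc_concentration(5.0, 0.2, 0.8) == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert itc_concentration(5.0, 0.2, 0.8) == pytest.approx(0.943224, abs=1e-6)

    @pytest.mark.parametrize("t", [0.5, 2.0, 10.0])
    def test_vanishing_clearance_limit_is_ramp_integral(self, t):
        """As gamma -> 0 the curve degrades continuously to beta*t^2/2."""
        beta = 0.37
        assert itc_concentration(t, beta, 0.0) == pytest.approx(0.5 * beta * t**2, rel=1e-12)
        assert itc_concentration(t, beta, 1e-8) == pytest.approx(0.5 * beta * t**2, rel=1e-6)

    def test_strictly_increasing(self):
        t = np.linspace(0, 30, 3000)
        i = itc_concentration(t, 0.2, 0.8)
        assert np.all(np.diff(i) > 0)

    @pytest.mark.parametrize("kwargs", [dict(t=-1.0), dict(beta=-0.1), dict(gamma=-0.5)])
    def test_domain_errors(self, kwargs):
        args = dict(t=1.0, beta=0.2, gamma=0.8) | kwargs
        with pytest.raises(ValueError):
            itc_concentration(args["t"], args["beta"], args["gamma"])


class TestNetEnergy:
    def test_starts_at_innate_energy_exactly(self, ref_params):
        assert net_energy(0.0, ref_params) == ref_params.en0

    def test_cost_free_case_is_pure_benefit_quadratic(self):
        p = ModelParameters(mu=0.0, delta=0.0, kappa=0.42, en0=0.1)
        t = np.linspace(0, B, 50)
        np.testing.assert_allclose(net_energy(t, p), 0.1 + 0.5 * 0.42 * t**2, rtol=1e-14)

    def test_matches_ode_integration_of_energy_balance(self, ref_params):
        p = ref_params
        rhs = lambda t, y: [
            p.kappa * t - p.mu * itc_concentration(t, p.beta, p.gamma) - p.delta * t**2
        ]
        sol = solve_ivp(rhs, (0, 10), [p.en0], method="DOP853", rtol=1e-12, atol=1e-14)
        assert net_energy(10.0, p) == pytest.approx(sol.y[0, -1], abs=1e-8)

    def test_rate_is_derivative_of_energy(self, ref_params):
        """Central differences of EN agree with the analytic rate."""
        h = 1e-5
        for t in (0.5, 3.0, 8.0, 14.0):
            numeric = (net_energy(t + h, ref_params) - net_energy(t - h, ref_params)) / (2 * h)
            assert net_energy_rate(t, ref_params) == pytest.approx(numeric, abs=1e-8)

    def test_rate_sign_pattern(self, ref_params):
        assert net_energy_rate(0.0, ref_params) == 0.0
        assert net_energy_rate(0.1, ref_params) > 0   # benefit dominates early
        assert net_energy_rate(20.0, ref_params) < 0  # foraging cost dominates late

    def test_unimodal_rising_then_falling(self):
        """EN increases then decreases: once the curve turns down it
        never recovers (at most one sign change of the rate)."""
        for p in draw_parameter_sets(30, seed=11):
            t = np.linspace(0, 10 * p.b, 4000)
            rate = np.asarray(net_energy_rate(t[1:], p))
            signs = np.sign(rate[np.abs(rate) > 1e-12])
            assert np.count_nonzero(np.diff(signs) != 0) <= 1


class TestGridAndTrajectory:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            TimeGrid(np.array([-0.5, 1.0]))

    def test_trajectory_alignment_and_labels(self):
        grid = TimeGrid(np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="align"):
            Trajectory(grid, {"H": np.zeros(2)})
        with pytest.raises(ValueError, match="unknown state"):
            Trajectory(grid, {"X": np.zeros(3)})

    def test_frame_column_order(self, ref_params):
        grid = TimeGrid.regular(0.0, 1.0, 0.5)
        frame = evaluate_closed_forms(ref_params, grid).to_frame()
        assert list(frame.columns) == ["t", "H", "G", "F", "I", "EN"]


class TestIntegrateModel:
    def test_zero_dynamics_all_series_constant(self):
        p = ModelParameters(theta=0, alpha=0, beta=0, kappa=0, mu=0, delta=0, en0=0.7)
        grid = TimeGrid.regular(0.0, 14.0, 0.5)
        traj = integrate_model(p, grid)
        for label in ("H", "G", "F", "I"):
            np.testing.assert_allclose(traj[label], 0.0, atol=1e-12)
        np.testing.assert_allclose(traj["EN"], 0.7, atol=1e-10)

    def test_agrees_with_closed_forms_on_reference_set(self, ref_params):
        grid = TimeGrid.regular(0.0, ref_params.b, 0.01)
        numeric = integrate_model(ref_params, grid)
        closed = evaluate_closed_forms(ref_params, grid)
        for label in ("H", "G", "F", "I", "EN"):
            assert np.max(np.abs(numeric[label] - closed[label])) <= 1e-6, label

    def test_refuses_runaway_horizon(self, ref_params):
        grid = TimeGrid.regular(0.0, 11 * ref_params.b, 1.0)
        with pytest.raises(ValueError, match="horizon"):
            integrate_model(ref_params, grid)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    theta=st.floats(0.0, 1.0), alpha=st.floats(0.0, 1.0),
    beta=st.floats(0.0, 1.0), gamma=st.floats(0.1, 3.0),
)
def test_states_nonnegative_and_nondecreasing(theta, alpha, beta, gamma):
    """H, G, I never decrease during development for any non-negative rates."""
    t = np.linspace(0.0, B, 300)
    for series in (
        herbivory(t, theta, B),
        gls_ingestion(t, alpha, B),
        itc_concentration(t, beta, gamma),
    ):
        assert np.all(series >= 0)
        assert np.all(np.diff(series) >= -1e-15)


def test_time_unit_rescaling_preserves_dimensionless_outcomes():
    """Measuring time in hours instead of days (and rescaling every rate
    accordingly) leaves EN values and T/b unchanged."""
    from larvenet import find_stopping_time

    p = draw_parameter_sets(1, seed=202)[0]
    c = 24.0
    scaled = ModelParameters(
        theta=p.theta / c**2, alpha=p.alpha / c**2, eta=p.eta / c,
        beta=p.beta / c**2, gamma=p.gamma / c, kappa=p.kappa / c**2,
        mu=p.mu / c, delta=p.delta / c**3, en0=p.en0, b=p.b * c,
    )
    for t in (0.2 * p.b, 0.7 * p.b):
        assert net_energy(c * t, scaled) == pytest.approx(net_energy(t, p), rel=1e-10)
    r, rs = find_stopping_time(p), find_stopping_time(scaled)
    assert (r.T is None) == (rs.T is None)
    if r.T is not None:
        assert rs.T / scaled.b == pytest.approx(r.T / p.b, rel=1e-7)
        assert rs.survived == r.survived
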