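"""Unit and property tests of the two-compartment model core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cscdrift import (
    RateParams,
    State,
    closed_form,
    eigenvalues,
    limiting_ratio,
    limiting_ratio_algebraic,
    ode_rhs,
    percent_to_ratio,
    ratio_to_percent,
    ratio_trajectory,
)

rates = st.floats(min_value=0.0, max_value=0.5, allow_nan=False)


def integrate(params: RateParams, S0, D0, t_eval):
    """Independent numerical oracle: adaptive RK integration of the RHS."""

    def rhs(t, y):
        return [params.k1 * y[0] - params.a * y[0] + params.b * y[1],
                params.k2 * y[1] + params.a * y[0] - params.b * y[1]]

    sol = solve_ivp(rhs, (0.0, max(t_eval)), [S0, D0], rtol=1e-11,
                    atol=1e-12, t_eval=t_eval, method="DOP853")
    return sol.y


class TestOdeRhs:
    @pytest.mark.parametrize("params, state, expected", [
        (RateParams(0.2, 0.22, 0, 0), State(0, 1, 1), (0.2, 0.22)),
        (RateParams(0, 0, 0, 0), State(0, 5, 7), (0.0, 0.0)),
        (RateParams(0.2, 0.22, 0.01, 0.001), State(0, 100, 10),
         (0.2 * 100 - 0.01 * 100 + 0.001 * 10,
          0.22 * 10 + 0.01 * 100 - 0.001 * 10)),
    ])
    def test_direct_substitution(self, params, state, expected):
        assert ode_rhs(params, state) == pytest.approx(expected, rel=1e-14)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            State(t=0, S=0.0, D=1.0)
        with pytest.raises(ValueError):
            State(t=-1, S=1.0, D=0.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RateParams(k1=-0.1, k2=0, a=0, b=0)
        with pytest.raises(ValueError):
            RateParams(k1=math.nan, k2=0, a=0, b=0)


class TestEigenvalues:
    def test_decoupled_diagonal(self):
        assert eigenvalues(RateParams(0.2, 0.22, 0, 0)) == (0.22, 0.2)

    def test_symmetric_analytic(self):
        # equal growth and equal conversion: eigenvalues k and k - 2c
        lam = eigenvalues(RateParams(k1=0.3, k2=0.3, a=0.05, b=0.05))
        assert lam == pytest.approx((0.3, 0.2), rel=1e-12)

    def test_quadratic_formula_oracle(self, demo_params):
        # roots of x^2 - T x + Det with T = 0.409, Det = 0.0416
        T = (0.2 - 0.01) + (0.22 - 0.001)
        Det = (0.2 - 0.01) * (0.22 - 0.001) - 0.01 * 0.001
        root = math.sqrt(T * T - 4 * Det)
        expected = ((T + root) / 2, (T - root) / 2)
        assert eigenvalues(demo_params) == pytest.approx(expected, rel=1e-12)
        assert expected[0] == pytest.approx(0.21934, abs=5e-6)
        assert expected[1] == pytest.approx(0.18966, abs=5e-6)

    @given(k1=rates, k2=rates, a=rates, b=rates)
    def test_always_real_and_ordered(self, k1, k2, a, b):
        lam1, lam2 = eigenvalues(RateParams(k1, k2, a, b))
        assert lam1 >= lam2
        assert math.isfinite(lam1) and math.isfinite(lam2)


class TestClosedForm:
    def test_initial_condition(self, demo_params):
        cf = closed_form(demo_params, S0=96.2, D0=3.8)
        S0, D0 = cf.evaluate(0.0)
        assert S0 == pytest.approx(96.2, rel=1e-10)
        assert D0 == pytest.approx(3.8, rel=1e-10)

    def test_decoupled_limit(self):
        cf = closed_form(RateParams(0.25, 0.1, 0, 0), S0=1.0, D0=0.0)
        t = np.linspace(0, 40, 9)
        np.testing.assert_allclose(cf.S(t), np.exp(0.25 * t), rtol=1e-12)
        np.testing.assert_allclose(cf.D(t), 0.0, atol=0.0)

    def test_matches_numerical_oracle(self, demo_params):
        t_eval = [10.0, 50.0]
        y = integrate(demo_params, 96.2, 3.8, t_eval)
        cf = closed_form(demo_params, 96.2, 3.8)
        S, D = cf.evaluate(np.array(t_eval))
        np.testing.assert_allclose(S, y[0], rtol=1e-6)
        np.testing.assert_allclose(D, y[1], rtol=1e-6)

    def test_random_draws_match_oracle(self, rate_draws):
        t_eval = [0.5, 30.0, 150.0, 300.0]
        for params in rate_draws[:60]:
            y = integrate(params, 10.0, 2.0, t_eval)
            S, D = closed_form(params, 10.0, 2.0).evaluate(np.array(t_eval))
            scale = y[0] + y[1]
            assert np.all(np.abs(S - y[0]) <= 1e-6 * np.maximum(
                np.abs(y[0]), 1e-9 * scale))
            assert np.all(np.abs(D - y[1]) <= 1e-6 * np.maximum(
                np.abs(y[1]), 1e-9 * scale))

    def test_degenerate_eigenvalues_confluent(self):
        # b = 0 with k1 - a == k2: exactly repeated eigenvalue
        params = RateParams(k1=0.3, k2=0.2, a=0.1, b=0.0)
        cf = closed_form(params, S0=5.0, D0=1.0)
        assert cf.degenerate
        t_eval = [5.0, 25.0, 60.0]
        y = integrate(params, 5.0, 1.0, t_eval)
        S, D = cf.evaluate(np.array(t_eval))
        np.testing.assert_allclose(S, y[0], rtol=1e-6)
        np.testing.assert_allclose(D, y[1], rtol=1e-6)

    @given(k1=rates, k2=rates, a=rates, b=rates)
    def test_positivity(self, k1, k2, a, b):
        cf = closed_form(RateParams(k1, k2, a, b), S0=3.0, D0=0.5)
        t = np.linspace(0.0, 200.0, 41)
        S, D = cf.evaluate(t)
        assert np.all(S > 0)
        assert np.all(D >= 0)

    def test_invalid_initial_state(self, demo_params):
        with pytest.raises(ValueError):
            closed_form(demo_params, S0=0.0, D0=1.0)
        with pytest.raises(ValueError):
            closed_form(demo_params, S0=1.0, D0=-0.1)


class TestRatioTrajectory:
    def test_starts_at_r0(self, demo_params):
        rt = ratio_trajectory(demo_params, 0.0395)
        assert rt(0.0) == pytest.approx(0.0395, rel=1e-12)

    def test_matches_compartment_ratio_oracle(self, demo_params):
        r0 = 0.0395
        t_eval = [50.0, 100.0, 200.0]
        y = integrate(demo_params, 1.0, r0, t_eval)
        rt = ratio_trajectory(demo_params, r0)
        np.testing.assert_allclose(rt(np.array(t_eval)), y[1] / y[0],
                                   rtol=1e-6)

    def test_consistent_with_closed_form(self, rate_draws):
        t = np.linspace(0.0, 250.0, 26)
        for params in rate_draws[:40]:
            cf = closed_form(params, 7.0, 2.1)
            rt = ratio_trajectory(params, 2.1 / 7.0)
            np.testing.assert_allclose(rt(t), cf.D(t) / cf.S(t), rtol=1e-8)

    def test_fixed_point_is_constant(self, demo_params):
        r_star = limiting_ratio(demo_params)
        rt = ratio_trajectory(demo_params, r_star)
        t = np.linspace(0.0, 500.0, 51)
        np.testing.assert_allclose(rt(t), r_star, rtol=1e-9)

    def test_growth_rate_shift_invariance(self, demo_params):
        # r(t) depends on (k1, k2) only through k2 - k1
        t = np.linspace(0.0, 300.0, 31)
        base = ratio_trajectory(demo_params, 0.0395)(t)
        for c in (0.05, 0.3, 0.77):
            shifted = RateParams(demo_params.k1 + c, demo_params.k2 + c,
                                 demo_params.a, demo_params.b)
            np.testing.assert_allclose(
                ratio_trajectory(shifted, 0.0395)(t), base, rtol=1e-9)

    def test_monotone_approach_to_limit(self, demo_params):
        r_star = limiting_ratio(demo_params)
        for r0 in (0.0395, 5.0, 80.0):
            gap = np.abs(ratio_trajectory(demo_params, r0)(
                np.linspace(0.0, 400.0, 81)) - r_star)
            assert np.all(np.diff(gap) <= 1e-12 * (1 + gap[:-1]))

    def test_large_time_no_overflow(self, demo_params):
        rt = ratio_trajectory(demo_params, 0.0395)
        with np.errstate(over="raise"):
            value = rt(1e5)
        assert value == pytest.approx(limiting_ratio(demo_params), rel=1e-9)


class TestLimitingRatio:
    def test_symmetric_case_is_one(self):
        assert limiting_ratio(RateParams(0.3, 0.3, 0.02, 0.02)) == \
            pytest.approx(1.0, rel=1e-12)
        assert limiting_ratio_algebraic(RateParams(0.3, 0.3, 0.02, 0.02)) == \
            pytest.approx(1.0, rel=1e-12)

    def test_stem_dominant_no_seeding(self):
        # a = 0 with the CSC eigenvalue dominant: ratio dies out
        assert limiting_ratio(RateParams(k1=0.5, k2=0.1, a=0.0, b=0.05)) == 0.0

    def test_quadratic_oracle(self, demo_params):
        # positive root of 0.001 r^2 - 0.029 r - 0.01 = 0
        expected = np.max(np.roots([0.001, -0.029, -0.01]))
        assert limiting_ratio(demo_params) == pytest.approx(expected,
                                                            rel=1e-10)
        assert limiting_ratio_algebraic(demo_params) == pytest.approx(
            expected, rel=1e-10)
        assert expected == pytest.approx(29.3408, abs=5e-5)

    def test_algebraic_equals_eigenvalue_route(self, rate_draws):
        for params in rate_draws:
            r_eig = limiting_ratio(params)
            r_alg = limiting_ratio_algebraic(params)
            if math.isfinite(r_eig):
                assert r_alg == pytest.approx(r_eig, rel=1e-10, abs=1e-13)
            else:
                assert r_alg == r_eig or (math.isnan(r_alg)
                                          and math.isnan(r_eig))

    def test_decoupled_edge_cases(self):
        assert limiting_ratio(RateParams(0.1, 0.3, 0, 0)) == math.inf
        assert limiting_ratio(RateParams(0.3, 0.1, 0, 0)) == 0.0
        # b = 0 but the differentiated eigenvalue dominates: ratio diverges
        assert limiting_ratio(RateParams(0.2, 0.3, 0.01, 0)) == math.inf
        # b = 0 with the CSC eigenvalue dominant: finite triangular limit
        params = RateParams(0.5, 0.1, 0.05, 0)
        expected = 0.05 / (0.5 - 0.05 - 0.1)
        assert limiting_ratio(params) == pytest.approx(expected, rel=1e-12)
        assert limiting_ratio_algebraic(params) == pytest.approx(expected,
                                                                 rel=1e-12)


class TestPercentRatioConversion:
    @pytest.mark.parametrize("percent, ratio", [
        (96.2, 0.0395), (50.0, 1.0), (1.5, 65.6667)])
    def test_printed_values(self, percent, ratio):
        assert round(percent_to_ratio(percent), 4) == ratio

    @given(p=st.floats(min_value=1e-3, max_value=100.0))
    def test_round_trip(self, p):
        assert ratio_to_percent(percent_to_ratio(p)) == pytest.approx(
            p, abs=1e-12, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            percent_to_ratio(0.0)
        with pytest.raises(ValueError):
            percent_to_ratio(101.0)
        with pytest.raises(ValueError):
            ratio_to_percent(-0.5)
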