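"""Unit and property tests for the single-trial decision models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

import riskmotor as rm
from riskmotor.errors import (
    InconsistentInputError,
    InvalidParameterError,
    RiskBreakdownError,
)

F0 = rm.CostFunction(0.0, 0.0, "F0")


def numeric_stress(r, mean, var, Q, theta, cost):
    """Quadrature oracle: -(2/theta)*log E[exp(-(theta/2)*Q*(x-r)^2)] + c(r).

    For theta < 0 the integrand's effective Gaussian width is
    1/sqrt(1/var + theta*Q) (wider than sqrt(var)), so the integration
    window is chosen from that combined precision.
    """
    sd = math.sqrt(var)
    sd_eff = 1.0 / math.sqrt(1.0 / var + theta * Q)

    def integrand(x):
        # single exp keeps the two competing quadratics from overflowing
        expo = -0.5 * ((x - mean) / sd) ** 2 - 0.5 * theta * Q * (x - r) ** 2
        return math.exp(expo) / (sd * math.sqrt(2 * math.pi))

    lo = min(mean, r) - 14 * max(sd, sd_eff)
    hi = max(mean, r) + 14 * max(sd, sd_eff)
    val, _ = quad(integrand, lo, hi, limit=400)
    return -(2.0 / theta) * math.log(val) + cost.c0 + cost.c1 * r


def numeric_argmin_stress(belief, Q, theta, cost):
    m = float(np.mean(belief.mean))
    res = minimize_scalar(
        lambda r: rm.stress_value(r, belief, Q, theta, cost),
        bounds=(m - 40.0, m + 40.0),
        method="bounded",
        options={"xatol": 1e-9, "maxiter": 500},
    )
    return res.x


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "obs, sigma_p, sigma_o, mean, var",
        [
            (0.0, 1.0, 1.0, 0.0, 0.5),
            (None, 2.0, math.inf, 0.0, 4.0),
            (3.0, 2.0, 1.0, 2.4, 0.8),
            (5.0, 2.0, 0.0, 5.0, 0.0),
        ],
    )
    def test_closed_form(self, obs, sigma_p, sigma_o, mean, var):
        b = rm.posterior_update(obs, sigma_p, sigma_o)
        assert b.mean == pytest.approx(mean)
        assert b.variance == pytest.approx(var)

    def test_matches_grid_integration(self):
        """Posterior moments agree with numerical integration of
        prior x likelihood on a fine grid."""
        o, sp, so = 3.0, 2.0, 1.0
        x = np.linspace(-15, 15, 200001)
        post = np.exp(-0.5 * (x / sp) ** 2) * np.exp(-0.5 * ((o - x) / so) ** 2)
        post /= np.trapezoid(post, x)
        mean = np.trapezoid(x * post, x)
        var = np.trapezoid((x - mean) ** 2 * post, x)
        b = rm.posterior_update(o, sp, so)
        assert b.mean == pytest.approx(mean, abs=1e-8)
        assert b.variance == pytest.approx(var, abs=1e-6)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            rm.posterior_update(0.0, -1.0, 1.0)
        with pytest.raises(InconsistentInputError):
            rm.posterior_update(1.0, 1.0, math.inf)
        with pytest.raises(InconsistentInputError):
            rm.posterior_update(None, 1.0, 1.0)

    def test_vectorised_observations(self):
        obs = np.array([-1.0, 0.0, 2.0])
        b = rm.posterior_update(obs, 2.0, 1.0)
        np.testing.assert_allclose(b.mean, 0.8 * obs)


class TestCosts:
    @pytest.mark.parametrize(
        "r, mean, var, Q, c0, c1, expected",
        [
            (0.5, 0.5, 0.0, 3.0, 0.0, 0.0, 0.0),
            (0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0),
            (1.0, 0.0, 0.5, 2.0, 0.3, 0.5, 3.8),
        ],
    )
    def test_expected_cost(self, r, mean, var, Q, c0, c1, expected):
        cost = rm.CostFunction(c0, c1, "FL" if c1 else "F0")
        assert rm.expected_cost(r, rm.PosteriorBelief(mean, var), Q, cost) == (
            pytest.approx(expected)
        )

    def test_expected_cost_monte_carlo(self):
        """Closed form matches the Monte-Carlo average of the trial cost."""
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, math.sqrt(0.5), 10**6)
        cost = rm.CostFunction(0.3, 0.5, "FL")
        mc = np.mean(2.0 * (x - 1.0) ** 2 + cost(1.0))
        closed = rm.expected_cost(1.0, rm.PosteriorBelief(0.0, 0.5), 2.0, cost)
        assert closed == pytest.approx(mc, rel=3e-3)

    def test_cost_function_invariants(self):
        with pytest.raises(InvalidParameterError):
            rm.CostFunction(1.0, 0.5, "F0")  # F0 must be free
        with pytest.raises(InvalidParameterError):
            rm.CostFunction(0.0, 0.0, "XX")


class TestRiskNeutral:
    def test_examples(self):
        belief = rm.PosteriorBelief(1.0, 0.7)
        assert rm.risk_neutral_response(belief, 1.0, F0) == pytest.approx(1.0)
        cost = rm.CostFunction(0.0, 0.5, "FL")
        assert rm.risk_neutral_response(belief, 1.0, cost) == pytest.approx(0.75)
        # dominant hit cost: bias vanishes
        assert rm.risk_neutral_response(belief, 1e9, cost) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            rm.risk_neutral_response(belief, 0.0, cost)

    def test_matches_numeric_minimiser(self):
        belief = rm.PosteriorBelief(1.0, 0.7)
        cost = rm.CostFunction(0.0, 0.5, "FL")
        res = minimize_scalar(
            lambda r: rm.expected_cost(r, belief, 1.0, cost),
            bounds=(-20, 20), method="bounded", options={"xatol": 1e-10},
        )
        assert rm.risk_neutral_response(belief, 1.0, cost) == (
            pytest.approx(res.x, abs=1e-7)
        )


class TestStress:
    def test_small_theta_limit(self):
        belief = rm.PosteriorBelief(0.4, 1.3)
        cost = rm.CostFunction(0.2, 0.8, "FL")
        for r in (-1.0, 0.0, 2.5):
            a = rm.stress_value(r, belief, 2.0, 1e-9, cost)
            b = rm.expected_cost(r, belief, 2.0, cost)
            assert a == pytest.approx(b, abs=1e-6)

    def test_log2_example(self):
        belief = rm.PosteriorBelief(0.0, 1.0)
        assert rm.stress_value(0.0, belief, 1.0, 1.0, F0) == pytest.approx(math.log(2))
        assert rm.stress_value(0.0, belief, 1.0, 1.0, F0) == pytest.approx(
            numeric_stress(0.0, 0.0, 1.0, 1.0, 1.0, F0), rel=1e-10
        )

    def test_breakdown(self):
        belief = rm.PosteriorBelief(0.0, 1.0)
        with pytest.raises(RiskBreakdownError):
            rm.stress_value(0.0, belief, 1.0, -1.0, F0)
        with pytest.raises(RiskBreakdownError):
            rm.risk_sensitive_response(belief, 1.0, -1.5, F0)

    @pytest.mark.parametrize("theta", [-0.3, 0.25, 1.0, 2.0])
    @pytest.mark.parametrize("var", [0.2, 1.0, 3.0])
    def test_closed_form_vs_quadrature(self, theta, var):
        """The exponential-utility integral evaluated numerically agrees
        with the closed form to 1e-8 relative tolerance."""
        cost = rm.CostFunction(0.1, -0.7, "FR")
        belief = rm.PosteriorBelief(0.6, var)
        for r, Q in [(-0.5, 0.5), (0.6, 1.0), (1.7, 2.0)]:
            if 1 + theta * Q * var <= 0.05:
                continue
            closed = rm.stress_value(r, belief, Q, theta, cost)
            numeric = numeric_stress(r, 0.6, var, Q, theta, cost)
            assert closed == pytest.approx(numeric, rel=1e-8)


class TestRiskSensitiveResponse:
    def test_reductions(self):
        cost = rm.CostFunction(0.0, 1.0, "FL")
        belief = rm.PosteriorBelief(0.3, 1.7)
        assert rm.risk_sensitive_response(belief, 2.0, 0.0, cost) == pytest.approx(
            rm.risk_neutral_response(belief, 2.0, cost)
        )
        sharp = rm.PosteriorBelief(0.3, 0.0)
        for theta in (-5.0, 0.0, 3.0):
            assert rm.risk_sensitive_response(sharp, 2.0, theta, cost) == (
                pytest.approx(rm.risk_neutral_response(sharp, 2.0, cost))
            )

    def test_frozen_example(self):
        cost = rm.CostFunction(0.0, 1.0, "FL")
        belief = rm.PosteriorBelief(0.0, 1.0)
        assert rm.risk_sensitive_response(belief, 1.0, 0.5, cost) == pytest.approx(-0.75)

    def test_continuity_at_zero(self):
        cost = rm.CostFunction(0.0, 0.9, "FL")
        belief = rm.PosteriorBelief(-0.2, 2.0)
        a = rm.risk_sensitive_response(belief, 3.0, 1e-8, cost)
        b = rm.risk_neutral_response(belief, 3.0, cost)
        assert abs(a - b) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=st.floats(-0.5, 2.0),
        Q=st.floats(0.1, 1e3),
        var=st.floats(0.0, 4.0),
        c1=st.floats(-2.0, 2.0),
        mean=st.floats(-3.0, 3.0),
    )
    def test_oracle_equivalence(self, theta, Q, var, c1, mean):
        """Closed-form minimiser agrees with numerical minimisation of the
        stress function everywhere the transform is well posed."""
        if 1.0 + theta * Q * var <= 1e-2:
            return
        cost = rm.CostFunction(0.0, c1, "FL" if c1 >= 0 else "FR")
        belief = rm.PosteriorBelief(mean, var)
        closed = rm.risk_sensitive_response(belief, Q, theta, cost)
        assert abs(closed - numeric_argmin_stress(belief, Q, theta, cost)) < 1e-6


class TestPredictions:
    def setup_method(self):
        self.params = rm.ModelParams(sigma_p=1.0, Q=1e6, theta=0.5)
        self.cost = rm.CostFunction(0.0, 1.0, "FL")

    def test_slope_limits(self):
        s_full, _ = rm.predicted_slope_intercept(
            self.params, rm.FeedbackCondition.full(), self.cost
        )
        s_none, _ = rm.predicted_slope_intercept(
            self.params, rm.FeedbackCondition.none(), self.cost
        )
        assert s_full == pytest.approx(0.0)
        assert s_none == pytest.approx(1.0)

    def test_blur_example(self):
        s, i = rm.predicted_slope_intercept(
            self.params, rm.FeedbackCondition.blur(1.0), self.cost
        )
        assert s == pytest.approx(0.5)
        assert i == pytest.approx(0.125, abs=1e-5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.05, 5.0), st.floats(0.05, 5.0))
    def test_slope_monotone_in_cue_noise(self, so1, so2):
        lo, hi = sorted((so1, so2))
        if hi - lo < 1e-9:
            return
        s_lo, i_lo = rm.predicted_slope_intercept(
            self.params, rm.FeedbackCondition.blur(lo), self.cost
        )
        s_hi, i_hi = rm.predicted_slope_intercept(
            self.params, rm.FeedbackCondition.blur(hi), self.cost
        )
        assert s_lo < s_hi
        assert abs(i_lo) < abs(i_hi)  # theta*c1 != 0

    def test_intercept_mirror_and_force_invariance(self):
        fb = rm.FeedbackCondition.blur(1.5)
        fl = rm.CostFunction(2.0, 0.5, "FL")
        fr = rm.CostFunction(2.0, -0.5, "FR")
        s_fl, i_fl = rm.predicted_slope_intercept(self.params, fb, fl)
        s_fr, i_fr = rm.predicted_slope_intercept(self.params, fb, fr)
        s_f0, i_f0 = rm.predicted_slope_intercept(self.params, fb, F0)
        assert s_fl == s_fr == s_f0  # slope independent of force
        assert i_fl == pytest.approx(-i_fr)
        assert i_f0 == pytest.approx(0.0)


class TestHitProbability:
    def test_certain_limits(self):
        params = rm.ModelParams(sigma_p=1.0, Q=10.0, theta=0.3, sigma_m=0.5,
                                halfwidth=1e9)
        fb = rm.FeedbackCondition.blur(1.0)
        assert rm.hit_probability(params, fb, F0) == pytest.approx(1.0)
        perfect = rm.ModelParams(sigma_p=1.0, Q=10.0, theta=0.0, sigma_m=0.0,
                                 halfwidth=0.5)
        assert rm.hit_probability(perfect, rm.FeedbackCondition.full(), F0) == 1.0

    def test_monotone_in_cue_noise(self):
        params = rm.ModelParams(sigma_p=1.0, Q=100.0, theta=0.4, sigma_m=0.2,
                                halfwidth=0.5)
        cost = rm.CostFunction(0.0, 0.4, "FL")
        sigmas = [0.0, 0.3, 1.0, 2.0, 10.0]
        conds = [rm.FeedbackCondition.full()] + [
            rm.FeedbackCondition.blur(s) for s in sigmas[1:]
        ] + [rm.FeedbackCondition.none()]
        probs = [rm.hit_probability(params, fb, cost) for fb in conds]
        assert all(a >= b - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_matches_monte_carlo(self):
        """Closed form within 3 s.e. of a simulated estimate."""
        params = rm.ModelParams(sigma_p=1.0, Q=1e4, theta=0.0, sigma_m=0.2,
                                halfwidth=0.5)
        fb = rm.FeedbackCondition.blur(1.0)
        closed = rm.hit_probability(params, fb, F0)
        rng = np.random.default_rng(99)
        n = 200_000
        x = rng.normal(0, 1.0, n)
        o = x + rng.normal(0, 1.0, n)
        belief = rm.posterior_update(o, 1.0, 1.0)
        r = rm.risk_sensitive_response(belief, params.Q, params.theta, F0)
        r = r + rng.normal(0, 0.2, n)
        p_hat = np.mean(np.abs(r - x) <= 0.5)
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(closed - p_hat) < 3 * se

    def test_invalid_halfwidth(self):
        with pytest.raises(InvalidParameterError):
            rm.ModelParams(sigma_p=1.0, Q=1.0, halfwidth=-1.0)
        finite = rm.ModelParams(sigma_p=1.0, Q=1.0, halfwidth=1.0)
        assert rm.hit_probability(finite, rm.FeedbackCondition.none(), F0) < 1.0
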