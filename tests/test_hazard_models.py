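"""Hazard evaluation, cumulative hazards, and inverse-transform sampling."""

import numpy as np
import pytest
from scipy.integrate import quad

import gbtrial as g
from gbtrial.hazard_models import HazardSpec, fit_super_coefficients


@pytest.fixture(scope="module")
def super_model():
    return g.sample_super_model_prior([0, 10, 20, 30, 40], (0.0, 0.5), rng=42)


class TestEvaluateHazard:
    @pytest.mark.parametrize(
        "spec, t, x, expected",
        [
            (g.exponential_spec(0.1), 5.0, 1, 0.1),            # beta=0 gives baseline
            (g.weibull_spec(0.1, 1.0), 17.3, 0, 0.1),          # shape 1 reduces to exponential
            (g.exponential_spec(0.1, beta=np.log(2)), 5.0, 1, 0.2),  # hazard ratio 2
            (g.piecewise_spec([0.1, 0.3], cutpoints=[10.0]), 12.0, 0, 0.3),
        ],
    )
    def test_closed_forms(self, spec, t, x, expected):
        assert g.evaluate_hazard(spec, t, x) == pytest.approx(expected)

    def test_domain_errors(self):
        spec = g.exponential_spec(0.1, t_max=40)
        with pytest.raises(ValueError):
            g.evaluate_hazard(spec, -1.0, 0)
        with pytest.raises(ValueError):
            g.evaluate_hazard(spec, 41.0, 0)
        with pytest.raises(ValueError):
            g.exponential_spec(-0.1)
        with pytest.raises(ValueError):
            g.weibull_spec(0.1, -1.0)


class TestCumulativeHazard:
    @pytest.mark.parametrize(
        "spec, t, expected",
        [
            (g.exponential_spec(0.1), 10.0, 1.0),
            (g.weibull_spec(0.05, 2.0), 4.0, 0.8),
            (g.piecewise_spec([0.1, 0.3], cutpoints=[10.0]), 15.0, 1.0 + 1.5),
        ],
    )
    def test_closed_forms(self, spec, t, expected):
        assert g.cumulative_hazard(spec, t, 0) == pytest.approx(expected)

    def test_super_matches_quadrature(self, super_model):
        spec = g.super_spec(super_model, beta=0.0, t_max=40)
        expected = quad(lambda t: g.evaluate_hazard(spec, t, 0), 0, 20, limit=400)[0]
        assert g.cumulative_hazard(spec, 20.0, 0) == pytest.approx(expected, rel=1e-8)

    def test_floored_cubic_matches_quadrature(self):
        # a polynomial that dips below zero exercises the flooring
        knots = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        coefs = np.array([0.4, -0.08, 0.004, -5e-5])  # negative near t=10
        sm = g.SuperModelSpec(knots, np.polynomial.polynomial.polyval(knots, coefs), coefs)
        spec = g.super_spec(sm, beta=0.0, t_max=40)
        assert np.any(sm.polynomial(np.linspace(0, 40, 400)) < 0), "fixture should dip below 0"
        expected = quad(lambda t: g.evaluate_hazard(spec, t, 0), 0, 40, limit=800)[0]
        assert g.cumulative_hazard(spec, 40.0, 0) == pytest.approx(expected, rel=1e-7)

    @pytest.mark.parametrize("family", ["exponential", "weibull", "super", "piecewise"])
    def test_monotone_and_nonnegative(self, family, super_model):
        spec = {
            "exponential": g.exponential_spec(0.07),
            "weibull": g.weibull_spec(0.05, 1.7),
            "super": g.super_spec(super_model),
            "piecewise": g.piecewise_spec([0.1, 0.02, 0.3, 0.05, 0.2, 0.1]),
        }[family]
        t = np.linspace(0, spec.t_max, 500)
        H = g.cumulative_hazard(spec, t, 1)
        assert H[0] == 0.0
        assert np.all(np.diff(H) >= 0)
        assert np.all(g.evaluate_hazard(spec, t, 1) >= 0)
        S = np.exp(-H)
        assert np.all((S > 0) & (S <= 1)) and np.all(np.diff(S) <= 0)


class TestSampling:
    def test_exponential_median(self):
        spec = g.exponential_spec(0.1)
        assert g.sample_event_time(spec, 0, 0.5) == pytest.approx(np.log(2) / 0.1)

    def test_weibull_inverse(self):
        spec = g.weibull_spec(0.1, 2.0)
        assert g.sample_event_time(spec, 0, np.exp(-0.9)) == pytest.approx(3.0)

    def test_beyond_horizon_is_inf(self):
        spec = g.exponential_spec(0.001, t_max=10)
        # -log(u) = 27.6 >> H(t_max) = 0.01: event falls past the horizon
        assert np.isinf(g.sample_event_time(spec, 0, 1e-12))

    def test_u_domain_error(self):
        spec = g.exponential_spec(0.1)
        for u in (0.0, 1.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                g.sample_event_time(spec, 0, u)

    def test_weibull_shape1_identical_to_exponential(self, rng):
        u = rng.uniform(size=1000)
        e = g.sample_event_time(g.exponential_spec(0.08), np.zeros(1000, int), u)
        w = g.sample_event_time(g.weibull_spec(0.08, 1.0), np.zeros(1000, int), u)
        np.testing.assert_allclose(e, w, rtol=1e-12)

    @pytest.mark.parametrize("family", ["exponential", "weibull", "super", "piecewise"])
    def test_sampled_cdf_matches_cumulative_hazard(self, family, super_model, rng):
        spec = {
            "exponential": g.exponential_spec(0.07, beta=-0.3),
            "weibull": g.weibull_spec(0.03, 1.6, beta=-0.3),
            "super": g.super_spec(super_model, beta=-0.3),
            "piecewise": g.piecewise_spec([0.1, 0.02, 0.3, 0.05, 0.2, 0.1], beta=-0.3),
        }[family]
        n = 100_000
        x = np.ones(n, int)
        t = g.sample_event_time(spec, x, rng.uniform(size=n))
        finite = np.isfinite(t)
        ts = np.sort(t[finite])
        emp = np.arange(1, ts.size + 1) / n
        theo = 1.0 - np.exp(-g.cumulative_hazard(spec, ts, 1))
        assert np.max(np.abs(emp - theo)) < 0.01

    def test_hazard_ratio_recovered(self, rng):
        beta = -0.5
        n = 1_000_000
        spec = g.exponential_spec(0.05, beta=beta, t_max=1e9)
        t0 = g.sample_event_time(spec, np.zeros(n // 2, int), rng.uniform(size=n // 2))
        t1 = g.sample_event_time(spec, np.ones(n // 2, int), rng.uniform(size=n // 2))
        ratio = (1.0 / t1.mean()) / (1.0 / t0.mean())
        assert ratio == pytest.approx(np.exp(beta), rel=0.02)


class TestTruncatedSampling:
    def test_memoryless_exponential(self):
        spec = g.exponential_spec(0.1, t_max=1000)
        z = g.sample_truncated_event_time(spec, 0, 4.0, 0.5)
        assert z == pytest.approx(4.0 + np.log(2) / 0.1)

    def test_u_near_one_returns_y_star(self):
        spec = g.weibull_spec(0.05, 1.5)
        z = g.sample_truncated_event_time(spec, 0, 7.0, 1 - 1e-14)
        assert z > 7.0 and z == pytest.approx(7.0, abs=1e-4)

    def test_weibull_truncated_closed_form(self):
        spec = g.weibull_spec(0.1, 2.0)
        z = g.sample_truncated_event_time(spec, 0, 3.0, np.exp(-0.7))
        # solves 0.1 z^2 = 0.9 + 0.7
        assert z == pytest.approx(4.0, abs=1e-5)

    @pytest.mark.parametrize("family", ["exponential", "weibull", "super", "piecewise"])
    def test_strictly_greater_than_y_star(self, family, super_model, rng):
        spec = {
            "exponential": g.exponential_spec(0.3),
            "weibull": g.weibull_spec(0.1, 0.7),
            "super": g.super_spec(super_model),
            "piecewise": g.piecewise_spec([0.4, 0.02, 0.3, 0.05, 0.2, 0.1]),
        }[family]
        ys = rng.uniform(0, spec.t_max * 0.95, size=2000)
        u = rng.uniform(size=2000)
        x = (rng.uniform(size=2000) < 0.5).astype(int)
        z = g.sample_truncated_event_time(spec, x, ys, u)
        assert np.all(z > ys)


class TestSuperModelPrior:
    def test_constant_knot_values_give_constant_polynomial(self):
        coefs = fit_super_coefficients([0, 10, 20, 30, 40], np.full(5, 0.2))
        assert coefs[0] == pytest.approx(0.2, abs=1e-10)
        np.testing.assert_allclose(coefs[1:], 0.0, atol=1e-12)

    def test_least_squares_residual_orthogonal_to_design(self):
        sm = g.sample_super_model_prior([0, 10, 20, 30, 40], (0.0, 0.5), rng=7)
        design = np.vander(sm.knots, 4, increasing=True)
        residual = sm.knot_values - design @ sm.coefficients
        # normal equations: residual orthogonal to each design column
        # (scaled by column norm; the t^3 column reaches 6.4e4)
        scaled = design.T @ residual / np.linalg.norm(design, axis=0)
        np.testing.assert_allclose(scaled, 0.0, atol=1e-10)

    def test_prior_draws_show_variety_of_shapes(self):
        # flat, monotone and non-monotone baselines should all occur
        rng = np.random.default_rng(3)
        shapes = set()
        t = np.linspace(0, 40, 200)
        for _ in range(10):
            sm = g.sample_super_model_prior([0, 10, 20, 30, 40], (0.0, 0.5), rng=rng)
            h = np.maximum(1e-6, sm.polynomial(t))
            d = np.diff(h)
            if h.max() - h.min() < 0.1:
                shapes.add("flat")
            elif np.all(d >= 0) or np.all(d <= 0):
                shapes.add("monotone")
            else:
                shapes.add("non-monotone")
        assert {"monotone", "non-monotone"} <= shapes or {"flat", "non-monotone"} <= shapes

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            fit_super_coefficients([0.0, 10.0], [0.1, 0.2])

    def test_value_range_validation(self):
        with pytest.raises(ValueError):
            g.sample_super_model_prior([0, 10, 20, 30, 40], (0.5, 0.1), rng=0)


class TestSerialization:
    @pytest.mark.parametrize(
        "spec",
        [
            g.exponential_spec(0.04, beta=-0.2),
            g.weibull_spec(0.04, 1.5, beta=-0.5, t_max=36),
            g.piecewise_spec([0.1, 0.2, 0.05], cutpoints=[10.0, 25.0]),
        ],
    )
    def test_round_trip(self, spec, rng):
        again = HazardSpec.from_dict(spec.to_dict())
        t = rng.uniform(0, spec.t_max, 50)
        np.testing.assert_allclose(
            g.evaluate_hazard(spec, t, 1), g.evaluate_hazard(again, t, 1)
        )

    def test_super_round_trip(self):
        sm = g.sample_super_model_prior([0, 10, 20, 30, 40], (0.0, 0.5), rng=5)
        spec = g.super_spec(sm, beta=-0.1)
        again = HazardSpec.from_dict(spec.to_dict())
        t = np.linspace(0, 40, 100)
        np.testing.assert_allclose(
            g.cumulative_hazard(spec, t, 0), g.cumulative_hazard(again, t, 0)
        )
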