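"""Partial-likelihood loss and the general Bayesian posterior of beta."""

import numpy as np
import pytest

import gbtrial as g
from gbtrial.gb_inference import GBConfig

from helpers import naive_partial_loss, newton_mple, random_survival_sample, simulate_sample


@pytest.fixture(scope="module")
def medium_sample():
    rng = np.random.default_rng(77)
    spec = g.exponential_spec(0.05, beta=-0.4, t_max=1e6)
    return simulate_sample(spec, 400, rng, censor_time=30.0)


class TestPartialLogLoss:
    def test_known_values(self):
        data = g.SurvivalSample([1, 2, 3], [1, 1, 0], [1, 0, 1])
        # at beta=0 each event contributes log |R_i|
        assert g.partial_log_loss(data, 0.0) == pytest.approx(np.log(6), abs=1e-12)
        expected = np.log(2 * np.e + 1) - 1 + np.log(1 + np.e)
        assert g.partial_log_loss(data, 1.0) == pytest.approx(expected, abs=1e-12)
        assert g.partial_log_loss(data, 1.0) == pytest.approx(2.1752565, abs=1e-6)

    def test_single_subject_zero_for_all_beta(self):
        data = g.SurvivalSample([5.0], [1], [1])
        for beta in (-2.0, 0.0, 3.0):
            assert g.partial_log_loss(data, beta) == 0.0

    def test_zero_events_degenerate(self):
        data = g.SurvivalSample([1.0, 2.0], [0, 0], [0, 1])
        profile = g.partial_loss_profile(data)
        assert profile.degenerate
        assert g.partial_log_loss(data, 1.3) == 0.0

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_enumeration_oracle(self, ties, rng):
        for _ in range(25):
            data = random_survival_sample(rng, n=int(rng.integers(5, 60)), ties=ties)
            for beta in (-1.5, -0.3, 0.0, 0.7, 2.0):
                assert g.partial_log_loss(data, beta) == pytest.approx(
                    naive_partial_loss(data, beta), abs=1e-10
                )

    @pytest.mark.parametrize("transform", [lambda t: t**3, lambda t: np.log1p(t)])
    def test_rank_invariance(self, transform, rng):
        data = random_survival_sample(rng, n=80)
        warped = g.SurvivalSample(transform(data.times), data.events, data.arms)
        for beta in (-1.0, 0.2, 1.5):
            assert g.partial_log_loss(data, beta) == pytest.approx(
                g.partial_log_loss(warped, beta), abs=1e-10
            )

    def test_censored_at_event_time_stays_in_risk_set(self):
        # one event at t=2 and a censoring exactly at t=2: |R| = 2
        data = g.SurvivalSample([2.0, 2.0], [1, 0], [0, 1])
        assert g.partial_log_loss(data, 0.0) == pytest.approx(np.log(2))


class TestGeneralPosterior:
    def test_zero_events_returns_symmetric_prior(self):
        data = g.SurvivalSample([1.0, 2.0, 3.0], [0, 0, 0], [0, 1, 0])
        post = g.general_posterior(data, GBConfig())
        assert post.degenerate
        assert post.prob_lt_zero == pytest.approx(0.5, abs=1e-3)
        assert post.mode == pytest.approx(0.0, abs=1e-6)

    def test_mode_matches_newton_mple(self, rng):
        cfg = GBConfig(prior_sd=50.0)
        checked = 0
        for _ in range(30):
            data = random_survival_sample(rng)
            mple = newton_mple(data)
            if not np.isfinite(mple):
                continue
            post = g.general_posterior(data, cfg)
            prior_pull = abs(mple) / cfg.prior_sd**2  # vanishing but not zero
            assert abs(post.mode - mple) <= 1e-3 + 10 * prior_pull
            checked += 1
        assert checked >= 20

    def test_normalization(self, medium_sample):
        post = g.general_posterior(medium_sample)
        assert np.trapezoid(post.density, post.grid) == pytest.approx(1.0, abs=1e-6)

    def test_quantiles_bracket_mode_and_are_monotone(self, medium_sample):
        post = g.general_posterior(medium_sample)
        qs = post.quantile(np.array([0.025, 0.25, 0.5, 0.75, 0.975]))
        assert np.all(np.diff(qs) > 0)
        assert qs[0] < post.mode < qs[-1]

    def test_doubling_w_shrinks_sd_by_sqrt2(self, medium_sample):
        sd1 = g.general_posterior(medium_sample, GBConfig(w=1.0, prior_sd=100.0)).sd
        sd2 = g.general_posterior(medium_sample, GBConfig(w=2.0, prior_sd=100.0)).sd
        assert sd2 / sd1 == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_grid_widens_for_strong_effects(self):
        rng = np.random.default_rng(5)
        spec = g.exponential_spec(0.1, beta=-4.0, t_max=1e6)
        data = simulate_sample(spec, 400, rng, censor_time=50.0)
        post = g.general_posterior(data)
        assert post.grid.min() < -3.5  # default grid_lo is -3
        assert not post.boundary_warning
        assert post.mode == pytest.approx(-4.0, abs=1.0)

    def test_calibration_and_concentration_with_n(self):
        # posterior modes center on the true beta and tighten with n
        beta = -0.25
        sds = []
        for n in (250, 500, 1000):
            modes = []
            for r in range(200):
                rng = np.random.default_rng(1000 * n + r)
                spec = g.weibull_spec(0.05, 1.4, beta=beta, t_max=1e6)
                data = simulate_sample(spec, n, rng, censor_time=30.0)
                modes.append(g.general_posterior(data).mode)
            modes = np.asarray(modes)
            mc_se = modes.std(ddof=1) / np.sqrt(modes.size)
            assert abs(modes.mean() - beta) < 2 * mc_se + 0.01
            sds.append(modes.std(ddof=1))
        assert sds[0] > sds[1] > sds[2]


class TestLaplacePosterior:
    def test_zero_events_prior_gaussian(self):
        data = g.SurvivalSample([1.0, 2.0], [0, 0], [0, 1])
        post = g.laplace_posterior(data, GBConfig(prior_sd=3.0))
        assert post.mode == pytest.approx(0.0, abs=1e-5)
        assert post.sd == pytest.approx(3.0, rel=1e-3)

    def test_close_to_grid_for_large_n(self, medium_sample):
        grid = g.general_posterior(medium_sample)
        lap = g.laplace_posterior(medium_sample)
        assert abs(lap.prob_lt_zero - grid.prob_lt_zero) < 0.01
        assert lap.mode == pytest.approx(grid.mode, abs=1e-3)

    def test_loss_is_concave(self, rng):
        # numeric second derivative of -l(beta) is <= 0 everywhere
        data = random_survival_sample(rng, n=60)
        profile = g.partial_loss_profile(data)
        h = 1e-4
        for beta in rng.uniform(-3, 3, size=25):
            curv = -(profile(beta + h) - 2 * profile(beta) + profile(beta - h)) / h**2
            assert curv <= 1e-8


class TestAgreementWithParametricAnalysis:
    def test_exponential_data_similar_prob_lt_zero(self):
        # with a correctly specified parametric model both posteriors
        # should give nearly the same evidence at n=1000
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            spec = g.exponential_spec(0.04, beta=-0.15, t_max=1e6)
            data = simulate_sample(spec, 1000, rng, censor_time=40.0)
            p_gb = g.general_posterior(data).prob_lt_zero
            p_exp = g.ExponentialAnalysis().posterior(data).prob_lt_zero
            assert abs(p_gb - p_exp) < 0.03


class TestLifelinesCrossCheck:
    def test_mode_matches_coxph_fit(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        cfg = GBConfig(prior_sd=100.0)
        for _ in range(5):
            data = random_survival_sample(rng, n=150)
            if newton_mple(data) is np.nan or not np.isfinite(newton_mple(data)):
                continue
            df = pd.DataFrame({"t": data.times, "e": data.events, "x": data.arms})
            cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
            mode = g.general_posterior(data, cfg).mode
            assert mode == pytest.approx(float(cph.params_.iloc[0]), abs=1e-3)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w": 0.0},
            {"w": -1.0},
            {"prior_sd": 0.0},
            {"grid_lo": 1.0, "grid_hi": -1.0},
            {"grid_points": 10},
            {"method": "exact"},
        ],
    )
    def test_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            GBConfig(**kwargs)

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            g.SurvivalSample([1.0, 2.0], [0, 1], [0])
        with pytest.raises(ValueError):
            g.SurvivalSample([1.0, -2.0], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            g.SurvivalSample([1.0, 2.0], [0, 2], [0, 1])
        with pytest.raises(ValueError):
            g.SurvivalSample([1.0, 2.0], [0, 1], [0, 3])
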