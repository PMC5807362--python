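"""Curve summaries, threshold crossings and censoring semantics."""

import numpy as np
import pytest

from bdchemo.mcmc import PosteriorDraws
from bdchemo.summaries import (
    DensePosterior,
    curve_summary,
    first_crossing,
    predict_rates,
    rate_percent_change,
    summary_concentration,
)


def _dense_from_curves(z, lam_draws, mu_draws, doses=None):
    return DensePosterior(
        np.asarray(z, float),
        np.asarray(lam_draws, float),
        np.asarray(mu_draws, float),
        np.asarray(z if doses is None else doses, float),
    )


def _draws_with_rates(doses, lam, mu, n=200):
    return PosteriorDraws(
        np.asarray(doses, float),
        np.tile(np.log(lam), (n, 1)), np.tile(np.log(mu), (n, 1)),
        alpha_lam=np.zeros(n), alpha_mu=np.zeros(n),
        tau2_lam=np.ones(n), tau2_mu=np.ones(n),
        l2_lam=np.full(n, 4.0), l2_mu=np.full(n, 4.0),
        theta=np.zeros(n), sigma2=np.ones(n),
    )


class TestFirstCrossing:
    def test_linear_interpolation(self):
        z = np.array([0.0, 1.0, 2.0])
        y = np.array([2.0, 1.0, 0.0])
        z_star, k = first_crossing(z, y, 0.5)
        assert z_star == pytest.approx(1.5) and k == 1

    def test_smallest_crossing_of_wiggly_curve(self):
        z = np.linspace(0, 4, 5)
        y = np.array([2.0, 0.5, 1.5, 0.5, 2.0])
        z_star, k = first_crossing(z, y, 1.0)
        assert z_star == pytest.approx(1 / 1.5 * 1.0, rel=1e-12)
        assert k >= 3

    def test_no_crossing(self):
        assert first_crossing([0, 1], [2.0, 3.0], 1.0) == (None, 0)


class TestCurveSummary:
    def test_identical_draws_have_zero_width(self):
        z = np.linspace(-9, -4, 20)
        lam = np.tile(np.full_like(z, 0.8), (150, 1))
        mu = np.tile(np.full_like(z, 0.3), (150, 1))
        cs = curve_summary(_dense_from_curves(z, lam, mu), n0_ref=1000)
        assert np.allclose(cs.m_lo, cs.m_hi)
        assert np.allclose(cs.m_mean, 1000 * np.exp(0.5))

    def test_matched_rates_give_flat_mean_curve(self):
        z = np.linspace(-9, -4, 10)
        r = np.tile(np.linspace(0.2, 1.2, 10), (120, 1))
        cs = curve_summary(_dense_from_curves(z, r, r), n0_ref=500)
        assert np.allclose(cs.m_mean, 500.0)

    def test_percentile_bands_match_analytic_quantiles(self, rng):
        z = np.array([-6.0, -5.0])
        n = 20_000
        phi = rng.normal(0.0, 0.25, size=(n, 2))
        lam = np.exp(phi)
        mu = np.full_like(lam, 1e-9)
        cs = curve_summary(_dense_from_curves(z, lam, mu), n0_ref=1.0)
        from scipy.stats import lognorm

        for j in range(2):
            lo, hi = lognorm.ppf([0.025, 0.975], 0.25)
            assert cs.lam_lo[j] == pytest.approx(lo, rel=0.03)
            assert cs.lam_hi[j] == pytest.approx(hi, rel=0.03)


class TestSummaryConcentration:
    def test_flat_doubling_curve_censors_everything(self):
        z = np.linspace(-9, -4, 30)
        lam = np.tile(np.full_like(z, np.log(2.0) + 0.3), (80, 1))
        mu = np.tile(np.full_like(z, 0.3), (80, 1))
        dense = _dense_from_curves(z, lam, mu)
        for kind in ("GI50", "TGI", "LC50"):
            s = summary_concentration(dense, kind, n0_ref=1000)
            assert s.censor == "above_range"
            assert s.fraction_censored == 1.0

    def test_exponential_decline_tgi_analytic_root(self):
        # m(z) = n0 exp(1 - (z - z_min)) crosses n0 exactly at z_min + 1
        z_min = -9.0
        z = np.linspace(z_min, z_min + 3, 301)
        delta = 1.0 - (z - z_min)
        lam = np.tile(delta + 1.5, (50, 1))  # lam - mu = delta
        mu = np.full_like(lam, 1.5)
        dense = _dense_from_curves(np.asarray(z), np.clip(lam, 1e-9, None), mu)
        s = summary_concentration(dense, "TGI", n0_ref=1000)
        assert np.log10(s.posterior_mean) == pytest.approx(z_min + 1, abs=2e-2)
        assert s.censor == "none"
        assert s.ci_low <= s.posterior_mean <= s.ci_high

    def test_threshold_ordering_on_decreasing_curve(self):
        # monotone decline from strong growth to strong kill: the three
        # thresholds must be ordered GI50 <= TGI <= LC50
        z = np.linspace(-9, -4, 120)
        delta = np.linspace(1.0, -1.5, z.size)
        lam = np.tile(np.clip(delta, 0, None) + 0.2, (60, 1))
        mu = lam - delta
        dense = _dense_from_curves(z, lam, mu)
        vals = {
            kind: summary_concentration(dense, kind, n0_ref=1000).posterior_mean
            for kind in ("GI50", "TGI", "LC50")
        }
        assert vals["GI50"] <= vals["TGI"] <= vals["LC50"]

    def test_shrinking_control_censors_gi50(self):
        z = np.linspace(-9, -4, 20)
        lam = np.tile(np.full_like(z, 0.1), (40, 1))
        mu = np.tile(np.full_like(z, 0.5), (40, 1))
        s = summary_concentration(_dense_from_curves(z, lam, mu), "GI50", 1000)
        assert s.fraction_censored == 1.0

    def test_ci_widens_as_draws_subsampled(self, rng):
        # order statistics sanity: fewer draws cannot tighten the interval
        z = np.linspace(-9, -4, 80)
        n = 4000
        centers = rng.normal(-6.5, 0.3, size=n)
        lam = 0.2 + 0.9 / (1 + np.exp((z[None, :] - centers[:, None]) / 0.3))
        mu = np.full_like(lam, 0.55)
        dense_full = _dense_from_curves(z, lam, mu)
        s_full = summary_concentration(dense_full, "TGI", 1000)
        sub = _dense_from_curves(z, lam[:200], mu[:200])
        s_sub = summary_concentration(sub, "TGI", 1000)
        w_full = np.log10(s_full.ci_high) - np.log10(s_full.ci_low)
        w_sub = np.log10(s_sub.ci_high) - np.log10(s_sub.ci_low)
        assert w_sub <= w_full * 1.3  # subsample CI similar or narrower-noisy
        assert w_full > 0


class TestRatePercentChange:
    def test_constant_rates_give_zero(self):
        draws = _draws_with_rates([-9, -6, -4], [0.5] * 3, [0.2] * 3)
        d_lam, d_mu = rate_percent_change(draws)
        assert d_lam == pytest.approx(0.0) and d_mu == pytest.approx(0.0)

    def test_doubling_rate_gives_plus_100(self):
        draws = _draws_with_rates([-9, -6, -4], [0.4, 0.6, 0.8], [0.2, 0.4, 0.6])
        d_lam, d_mu = rate_percent_change(draws)
        assert d_lam == pytest.approx(100.0)
        assert d_mu == pytest.approx(200.0)


class TestPredictRates:
    def test_dense_grid_contains_doses_and_positive_rates(self):
        doses = np.linspace(-9, -4, 9)
        draws = _draws_with_rates(doses, np.full(9, 0.7), np.full(9, 0.3), n=50)
        dense = predict_rates(draws, rng=np.random.default_rng(0))
        assert np.all(np.isin(doses, dense.z))
        assert np.all(dense.lam > 0) and np.all(dense.mu > 0)
        # at the tested doses the draws are passed through unchanged
        idx = np.searchsorted(dense.z, doses)
        assert np.allclose(dense.lam[:, idx], 0.7)
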