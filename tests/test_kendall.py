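"""Birth-death process math against closed forms and the Gillespie oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bdchemo.kendall import (
    BDPParams,
    alpha_beta,
    dose_moments,
    experiment_loglik,
    moments,
    simulate_bdp,
    simulate_bdp_batch,
    transition_probability,
)

RATES = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)


class TestAlphaBeta:
    def test_pure_death_limit(self):
        a, b = alpha_beta(BDPParams(0.0, 1.0), 1.0)
        assert a == pytest.approx(1 - math.exp(-1), abs=1e-12)
        assert b == 0.0

    def test_equal_rates_limit_matches_nearby_generic(self):
        a_lim, b_lim = alpha_beta(BDPParams(0.5, 0.5), 1.0)
        assert a_lim == pytest.approx(1 / 3, abs=1e-9)
        a_gen, b_gen = alpha_beta(BDPParams(0.5 + 1e-9, 0.5), 1.0)
        assert a_gen == pytest.approx(a_lim, abs=1e-6)
        assert b_gen == pytest.approx(b_lim, abs=1e-6)

    def test_zero_time(self):
        assert alpha_beta(BDPParams(1.3, 0.4), 0.0) == (0.0, 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            alpha_beta(BDPParams(1.0, 1.0), -0.1)

    @given(lam=RATES, mu=RATES, t=st.floats(min_value=0, max_value=3))
    @settings(max_examples=200, deadline=None)
    def test_probabilities_in_unit_interval(self, lam, mu, t):
        a, b = alpha_beta(BDPParams(lam, mu), t)
        assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0


class TestTransitionProbability:
    def test_single_cell_extinction_pure_death(self):
        p = transition_probability(1, 0, BDPParams(0.0, 1.0), 1.0)
        assert p == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_frozen_process_stays_put(self):
        assert transition_probability(3, 3, BDPParams(0.0, 0.0), 1.0) == 1.0
        assert transition_probability(3, 2, BDPParams(0.0, 0.0), 1.0) == 0.0

    def test_extinct_start_is_absorbing(self):
        assert transition_probability(0, 0, BDPParams(1.0, 1.0), 1.0) == 1.0
        assert transition_probability(0, 2, BDPParams(1.0, 1.0), 1.0) == 0.0

    def test_matches_direct_combinatorial_sum(self):
        # literal transcription of the alternating combinatorial formula,
        # stable for small a
        def direct(a, b, lam, mu, t=1.0):
            al, be = alpha_beta(BDPParams(lam, mu), t)
            g = 1 - al - be
            return sum(
                math.comb(a, j) * math.comb(a + b - j - 1, a - 1)
                * al ** (a - j) * be ** (b - j) * g**j
                for j in range(0, min(a, b) + 1)
            )

        for a, b in [(1, 2), (2, 3), (3, 0), (4, 7), (5, 5)]:
            for lam, mu in [(0.6, 0.3), (1.5, 0.7), (0.5, 0.5), (0.1, 1.0)]:
                expected = direct(a, b, lam, mu)
                got = transition_probability(a, b, BDPParams(lam, mu), 1.0)
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-14)

    @pytest.mark.parametrize("lam,mu", [(0.1, 0.1), (2.0, 2.0), (1.5, 0.7), (0.3, 1.8)])
    @pytest.mark.parametrize("a", [1, 7, 20])
    def test_distribution_sums_to_one(self, lam, mu, a):
        p = BDPParams(lam, mu)
        total = sum(transition_probability(a, b, p, 1.0) for b in range(4000))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_monte_carlo_agreement(self, rng):
        p = BDPParams(0.6, 0.3)
        n = 200_000
        k = simulate_bdp_batch(2, p, 1.0, size=n, rng=rng)
        for b in (0, 1, 2, 3, 5):
            phat = float(np.mean(k == b))
            se = math.sqrt(max(phat * (1 - phat), 1e-12) / n)
            assert transition_probability(2, b, p, 1.0) == pytest.approx(
                phat, abs=3.5 * se + 1e-6
            )


class TestMoments:
    def test_frozen(self):
        mp = moments(100, BDPParams(0.0, 0.0), 1.0)
        assert (mp.mean, mp.variance) == (100.0, 0.0)

    def test_equal_rates_variance_limit(self):
        mp = moments(100, BDPParams(0.5, 0.5), 1.0)
        assert mp.mean == pytest.approx(100.0)
        assert mp.variance == pytest.approx(100.0 * 1.0 * 1.0)

    def test_growth_mean(self):
        mp = moments(100, BDPParams(0.7, 0.2), 1.0)
        assert mp.mean == pytest.approx(100 * math.exp(0.5), rel=1e-12)

    def test_continuity_across_equal_rates(self):
        base = moments(500, BDPParams(0.8, 0.8), 1.0)
        for eps in (1e-7, 1e-6, 1e-5):
            near = moments(500, BDPParams(0.8 + eps, 0.8), 1.0)
            assert near.variance == pytest.approx(base.variance, rel=1e-4)
            assert near.mean == pytest.approx(base.mean, rel=1e-4)

    def test_variance_scales_with_turnover(self):
        # same mean, hugely different variance: the identifiability signal
        v_hot = moments(1000, BDPParams(1.0, 1.0), 1.0).variance
        v_cold = moments(1000, BDPParams(0.01, 0.01), 1.0).variance
        assert v_hot / v_cold == pytest.approx(100.0, rel=1e-12)

    def test_dose_moments_vectorised_matches_scalar(self):
        lam = np.array([0.7, 0.5, 0.2])
        mu = np.array([0.2, 0.5, 0.9])
        m, v = dose_moments(100.0, lam, mu)
        for i in range(3):
            mp = moments(100, BDPParams(lam[i], mu[i]), 1.0)
            assert m[i] == pytest.approx(mp.mean)
            assert v[i] == pytest.approx(mp.variance)


class TestLoglik:
    def test_observation_at_the_mean(self):
        m, v = dose_moments(1000.0, 0.3, 0.1)
        ll = experiment_loglik(
            [-5.0], [1000.0], [float(m) + 5.0], [], [0.3], [0.1], 5.0, 2.0
        )
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * (float(v) + 2.0)))

    def test_degenerate_process_reduces_to_iid_normal(self):
        x = np.array([998.0, 1004.0, 1001.0])
        ll = experiment_loglik(
            [-5, -5, -5], [1000] * 3, x, [], [0.0] * 3, [0.0] * 3, 0.0, 25.0
        )
        from scipy.stats import norm

        assert ll == pytest.approx(norm.logpdf(x, 1000, 5).sum())

    def test_matches_term_by_term_transcription(self, both_experiment):
        exp, truth = both_experiment
        lam = truth.lam_at_doses[exp.dose_index()]
        mu = truth.mu_at_doses[exp.dose_index()]
        theta, sigma2 = 30.0, 400.0
        from scipy.stats import norm

        expected = 0.0
        for zi, n0i, xi, li, mi in zip(exp.z, exp.n0, exp.x, lam, mu):
            mm, vv = dose_moments(n0i, li, mi)
            expected += norm.logpdf(xi, mm + theta, np.sqrt(vv + sigma2))
        for e in exp.background:
            expected += norm.logpdf(e, theta, np.sqrt(sigma2))
        got = experiment_loglik(exp.z, exp.n0, exp.x, exp.background, lam, mu, theta, sigma2)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_nonpositive_noise_variance_rejected(self):
        with pytest.raises(ValueError):
            experiment_loglik([-5], [100], [100], [], [0.1], [0.1], 0.0, 0.0)


class TestSimulator:
    def test_frozen_population(self, rng):
        k = simulate_bdp_batch(50, BDPParams(0.0, 0.0), 1.0, size=10, rng=rng)
        assert np.all(k == 50)

    def test_reproducible_under_seed(self):
        a = simulate_bdp(100, BDPParams(0.7, 0.2), 1.0, rng=123)
        b = simulate_bdp(100, BDPParams(0.7, 0.2), 1.0, rng=123)
        assert a == b

    def test_extinction_fraction_pure_death(self, rng):
        n = 100_000
        k = simulate_bdp_batch(1, BDPParams(0.0, 1.0), 1.0, size=n, rng=rng)
        phat = float(np.mean(k == 0))
        p = 1 - math.exp(-1)
        assert phat == pytest.approx(p, abs=4 * math.sqrt(p * (1 - p) / n))

    def test_moments_match_closed_form(self, rng):
        n = 50_000
        p = BDPParams(0.7, 0.2)
        k = simulate_bdp_batch(100, p, 1.0, size=n, rng=rng)
        mp = moments(100, p, 1.0)
        se_mean = math.sqrt(mp.variance / n)
        assert float(k.mean()) == pytest.approx(mp.mean, abs=4 * se_mean)
        se_var = mp.variance * math.sqrt(2.0 / (n - 1)) * 2  # loose kurtosis margin
        assert float(k.var(ddof=1)) == pytest.approx(mp.variance, abs=4 * se_var)

    def test_population_cap_raises(self, rng):
        with pytest.raises(OverflowError):
            simulate_bdp_batch(1000, BDPParams(5.0, 0.0), 2.0, size=2, rng=rng, cap=5000)
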