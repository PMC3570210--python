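"""Hurdle-model fitting and the combined likelihood-ratio test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from schurdle.core_data import ConfigError, ValidationError
from schurdle.hurdle import (
    HurdleParams,
    batch_combined_lrt,
    combined_lrt,
    fit_hurdle,
    permutation_pvalue,
    two_group_loglik,
)


def random_two_group(rng, n_max=40):
    """A random pair of non-negative et vectors with mixed zeros."""
    n0, n1 = rng.integers(3, n_max, 2)
    pi = rng.uniform(0.1, 0.95)
    mu, sg = rng.uniform(5, 25), rng.uniform(0.5, 3)
    g0 = np.where(rng.random(n0) < pi, np.abs(rng.normal(mu, sg, n0)), 0.0)
    g1 = np.where(rng.random(n1) < pi, np.abs(rng.normal(mu, sg, n1)), 0.0)
    return g0, g1


class TestFit:
    def test_direct_formulas(self):
        p = fit_hurdle([0.0, 0.0, 3.0, 5.0])
        assert p.pi == 0.5 and p.mu == 4.0 and p.sigma2 == 1.0

    def test_all_zero(self):
        p = fit_hurdle([0.0, 0.0])
        assert p.pi == 0.0 and math.isnan(p.mu) and math.isnan(p.sigma2)

    def test_constant_positive_is_degenerate(self):
        p = fit_hurdle([7.0, 7.0, 7.0])
        assert p.pi == 1.0 and p.sigma2 == 0.0 and p.degenerate

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            fit_hurdle([])


class TestLoglik:
    def test_bernoulli_term_vanishes_at_pi_one(self):
        g = np.array([4.0, 5.0, 6.0])
        p = fit_hurdle(g)
        ll = two_group_loglik(g, g, p, p)
        # all wells positive: the Bernoulli factor is log 1 = 0, only normal terms remain
        pos_ll = 2 * sum(
            -0.5 * math.log(2 * math.pi * p.sigma2) - (x - p.mu) ** 2 / (2 * p.sigma2) for x in g
        )
        assert ll == pytest.approx(pos_ll)

    def test_all_zero_loglik_is_zero(self):
        p = HurdleParams(pi=0.0, mu=float("nan"), sigma2=float("nan"))
        assert two_group_loglik([0.0, 0.0], [0.0], p, p) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mle_beats_perturbed_parameters(self, seed):
        rng = np.random.default_rng(seed)
        g0, g1 = random_two_group(rng)
        pooled = np.concatenate([g0, g1])
        fit = fit_hurdle(pooled)
        best = two_group_loglik(g0, g1, fit, fit)
        for dpi in (-0.1, 0.05, 0.1):
            for dmu in (-0.5, 0.3):
                pi = min(max(fit.pi + dpi, 1e-6), 1 - 1e-6)
                alt = HurdleParams(pi=pi, mu=fit.mu + dmu, sigma2=fit.sigma2 * 1.1)
                assert two_group_loglik(g0, g1, alt, alt) <= best + 1e-9


class TestCombinedLrt:
    def test_identical_groups_give_null_result(self):
        g = np.array([0.0, 3.0, 4.0, 5.0, 0.0])
        res = combined_lrt(g, g)
        assert res.lambda_combined == pytest.approx(0.0, abs=1e-12)
        assert res.p_asymptotic == pytest.approx(1.0)
        assert res.direction == 0

    def test_pure_frequency_difference(self):
        # 10/10 expressed vs 0/10: closed-form Bernoulli LRT with pooled pi = 1/2
        res = combined_lrt(np.full(10, 12.0), np.zeros(10))
        assert res.lambda_binom == pytest.approx(-2 * 20 * math.log(0.5), rel=1e-12)
        assert res.lambda_normal == 0.0
        assert res.direction == -1

    def test_pure_level_difference(self):
        res = combined_lrt(np.array([1.0, 2.0, 3.0]), np.array([5.0, 6.0, 7.0]))
        assert res.lambda_binom == 0.0
        assert res.lambda_normal == pytest.approx(6 * math.log(7), rel=1e-12)
        assert res.direction == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            combined_lrt([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_numerical_likelihood_maximization(self, seed):
        """Closed-form Lambda vs brute-force maximization of the likelihood."""
        rng = np.random.default_rng(seed)
        g0, g1 = random_two_group(rng)
        s0, s1 = (g0 > 0).sum(), (g1 > 0).sum()
        if min(s0, s1) < 2:  # keep the oracle's optimization well-posed
            g0[:2] = [8.0, 9.0]
            g1[:2] = [8.5, 9.5]

        def nll_h1(theta):
            p0, p1, m0, m1, ls = theta
            a = HurdleParams(p0, m0, math.exp(ls))
            b = HurdleParams(p1, m1, math.exp(ls))
            return -two_group_loglik(g0, g1, a, b)

        def nll_h0(theta):
            p, m, ls = theta
            a = HurdleParams(p, m, math.exp(ls))
            return -two_group_loglik(g0, g1, a, a)

        eps = 1e-9
        x1 = minimize(
            nll_h1,
            [max((g0 > 0).mean(), 0.05), max((g1 > 0).mean(), 0.05),
             g0[g0 > 0].mean(), g1[g1 > 0].mean(), 0.0],
            bounds=[(eps, 1 - eps)] * 2 + [(None, None)] * 2 + [(-8, 8)],
            method="L-BFGS-B",
        )
        pooled = np.concatenate([g0, g1])
        x0 = minimize(
            nll_h0,
            [max((pooled > 0).mean(), 0.05), pooled[pooled > 0].mean(), 0.0],
            bounds=[(eps, 1 - eps), (None, None), (-8, 8)],
            method="L-BFGS-B",
        )
        lam_oracle = 2 * (x0.fun - x1.fun)
        res = combined_lrt(g0, g1)
        assert res.lambda_combined == pytest.approx(lam_oracle, abs=5e-4)

    def test_decomposition_and_symmetry(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            g0, g1 = random_two_group(rng)
            r = combined_lrt(g0, g1)
            assert abs(r.lambda_combined - (r.lambda_binom + r.lambda_normal)) < 1e-8
            assert r.lambda_combined >= 0
            swapped = combined_lrt(g1, g0)
            assert swapped.lambda_combined == pytest.approx(r.lambda_combined, abs=1e-9)
            assert swapped.direction == -r.direction

    @given(st.integers(0, 10), st.integers(0, 10))
    @settings(deadline=None, max_examples=40)
    def test_degenerate_layouts_stay_finite(self, s0, s1):
        rng = np.random.default_rng(s0 * 11 + s1)
        g0 = np.concatenate([10 + rng.random(s0), np.zeros(10 - s0 if s0 <= 10 else 0)])
        g1 = np.concatenate([12 + rng.random(s1), np.zeros(10 - s1 if s1 <= 10 else 0)])
        r = combined_lrt(g0, g1)
        assert np.isfinite(r.lambda_combined)
        assert 0 < r.p_asymptotic <= 1

    def test_small_sample_flag(self):
        g0 = np.array([0.0] * 8 + [10.0, 11.0])
        g1 = np.array([0.0] * 8 + [12.0, 13.0])
        assert combined_lrt(g0, g1).small_sample_flag
        big0 = np.concatenate([np.zeros(10), 10 + np.arange(10.0)])
        assert not combined_lrt(big0, big0).small_sample_flag


class TestBatch:
    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(9)
        x0 = np.where(rng.random((50, 25)) < 0.4, 12 + rng.normal(0, 2, (50, 25)), 0.0)
        x1 = np.where(rng.random((50, 30)) < 0.5, 13 + rng.normal(0, 2, (50, 30)), 0.0)
        out = batch_combined_lrt(x0, x1)
        for i in range(50):
            r = combined_lrt(x0[i], x1[i])
            assert out["lambda_combined"][i] == pytest.approx(r.lambda_combined, abs=1e-9)
            assert out["lambda_binom"][i] == pytest.approx(r.lambda_binom, abs=1e-9)


class TestPermutation:
    def test_identical_groups_give_p_one(self):
        g = np.array([0.0, 3.0, 4.0, 0.0, 5.0])
        assert permutation_pvalue(g, g, B=99, seed=0) == 1.0

    def test_add_one_floor(self):
        g0 = np.zeros(12)
        g1 = np.full(12, 20.0)
        # the observed separation is unbeatable by almost any relabelling
        p = permutation_pvalue(g0, g1, B=199, seed=1)
        assert p <= 5 / 200

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        g0, g1 = random_two_group(rng)
        assert permutation_pvalue(g0, g1, 200, seed=5) == permutation_pvalue(g0, g1, 200, seed=5)

    def test_invalid_B(self):
        with pytest.raises(ConfigError):
            permutation_pvalue([1.0], [2.0], B=0)

    def test_agrees_with_chi2_for_large_samples(self):
        rng = np.random.default_rng(7)
        n = 120
        g0 = np.where(rng.random(n) < 0.4, rng.normal(15, 2, n), 0.0)
        g1 = np.where(rng.random(n) < 0.4, rng.normal(15, 2, n), 0.0)
        res = combined_lrt(g0, g1)
        p_perm = permutation_pvalue(g0, g1, B=4000, seed=3)
        mc_se = math.sqrt(res.p_asymptotic * (1 - res.p_asymptotic) / 4000)
        assert abs(p_perm - res.p_asymptotic) < 4 * mc_se + 0.01
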