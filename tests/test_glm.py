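"""NB GLM engine: size factors, fitting, dispersion, LRT, Wald, BH, shrinkage.

statsmodels' NB GLM (known alpha) serves as the independent fitting oracle.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from ntve.glm import (
    LN2,
    bh_adjust,
    estimate_dispersion_single,
    fit_nb_glm,
    lrt,
    moderate_dispersions,
    nb_loglik,
    nb_wald_de,
    one_vs_rest_lrt,
    shrink_lfc,
    size_factors_median_of_ratios,
    wald_pvalues,
)
from ntve.io import CountMatrix
from ntve.simulate import nb_sample, simulate_two_condition


def cm(values):
    return CountMatrix(pd.DataFrame(values))


class TestSizeFactors:
    def test_identical_samples_give_ones(self):
        s = size_factors_median_of_ratios(cm({"a": [3, 10, 7], "b": [3, 10, 7]}))
        assert np.allclose(s, 1.0)

    def test_doubled_sample_closed_form(self):
        s = size_factors_median_of_ratios(cm({"a": [2, 10, 40], "b": [4, 20, 80]}))
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_universally_positive_gene_errors(self):
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(cm({"a": [0, 5], "b": [5, 0]}))


class TestFitNbGlm:
    def test_intercept_only_closed_form(self, rng):
        """log(sum y / sum s): exact for equal offsets at any dispersion, and
        for arbitrary offsets in the Poisson limit."""
        y = rng.poisson(50, 30)
        fit = fit_nb_glm(y, np.ones((30, 1)), np.log(np.full(30, 1.7)), alpha=0.05)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(y.sum() / (30 * 1.7)), abs=1e-8)
        s = rng.uniform(0.5, 2.0, 30)
        fit = fit_nb_glm(y, np.ones((30, 1)), np.log(s), alpha=1e-8)
        # with unequal offsets the identity holds only as alpha -> 0; at
        # alpha = 1e-8 the NB MLE sits O(alpha * mu) away from it
        assert fit.coefficients[0] == pytest.approx(np.log(y.sum() / s.sum()), abs=1e-6)

    def test_all_zero_response_flagged(self):
        fit = fit_nb_glm(np.zeros(10), np.ones((10, 1)), None, 0.05)
        assert not fit.converged

    def test_matches_statsmodels_oracle(self, rng):
        """Coefficients, SEs and log-likelihood agree with statsmodels GLM."""
        for _ in range(10):
            n = 40
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            off = np.log(rng.uniform(0.5, 2, n))
            mu = np.exp(1.5 + 0.8 * x + off)
            alpha = 0.1
            y = nb_sample(rng, mu, alpha)
            if y.sum() == 0:
                continue
            mine = fit_nb_glm(y, X, off, alpha)
            ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=off).fit()
            assert np.allclose(mine.coefficients, ref.params, atol=1e-6)
            assert np.allclose(mine.log_likelihood, ref.llf, atol=1e-6)
            assert np.allclose(mine.standard_errors, ref.bse, rtol=0.05)

    def test_recovery_from_known_coefficients(self, rng):
        n = 200
        x = np.tile([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), x])
        betas = []
        for _ in range(50):
            y = nb_sample(rng, np.exp(np.log(300) + 0.7 * x), 0.05)
            betas.append(fit_nb_glm(y, X, None, 0.05).coefficients)
        bias = np.abs(np.mean(betas, axis=0) - [np.log(300), 0.7])
        assert bias.max() < 0.05


class TestDispersion:
    def test_poisson_counts_hit_floor(self, rng):
        X = np.ones((30, 1))
        alphas = [estimate_dispersion_single(rng.poisson(500, 30).astype(float), X) for _ in range(50)]
        assert np.mean(np.array(alphas) < 1e-3) >= 0.9

    def test_recovery_of_alpha(self, rng):
        X = np.ones((20, 1))
        alphas = [estimate_dispersion_single(nb_sample(rng, np.full(20, 500.0), 0.1), X) for _ in range(500)]
        assert 0.07 <= np.median(alphas) <= 0.13

    def test_constant_counts_at_floor(self):
        assert estimate_dispersion_single(np.full(10, 7.0), np.ones((10, 1))) == pytest.approx(1e-8)

    def test_moderation_pools_toward_consensus(self):
        alphas = np.array([0.01, 0.05, 0.05, 0.05, 0.4])
        svars = np.full(5, 1.0)
        mod = moderate_dispersions(alphas, svars, consensus=0.05)
        assert mod[0] > alphas[0] and mod[-1] < alphas[-1]  # extremes pulled in
        spread = np.ptp(np.log(mod))
        assert spread < np.ptp(np.log(alphas))


class TestLrt:
    def test_identical_models_lambda_zero(self):
        from ntve.glm import NBFitResult

        f = NBFitResult(np.zeros(1), np.ones(1), -10.0, 0.05, True, 3)
        lam, p = lrt(f, f, 1)
        assert lam == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        from ntve.glm import NBFitResult

        f = NBFitResult(np.zeros(2), np.ones(2), -10.0, 0.05, True, 3)
        r = NBFitResult(np.zeros(1), np.ones(1), -10.0 - 3.841 / 2, 0.05, True, 3)
        _, p = lrt(f, r, 1)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_poisson_limit_of_loglik(self, rng):
        y = rng.poisson(50, 100).astype(float)
        mu = np.full(100, 50.0)
        nb = nb_loglik(y, mu, 1e-8)
        pois = float(np.sum(sps.poisson.logpmf(y, mu)))
        assert abs(nb - pois) / abs(pois) < 1e-4


class TestWald:
    def test_greater_abs_boundary(self):
        _, p = wald_pvalues(np.array([1.0]), np.array([0.2]), "greaterAbs", theta=1.0)
        assert p[0] == pytest.approx(1.0)

    def test_less_abs_tiny_p_at_zero(self):
        _, p = wald_pvalues(np.array([0.0]), np.array([0.1]), "lessAbs", theta=1.0)
        assert p[0] == pytest.approx(sps.norm.cdf(-10.0), rel=1e-6)

    def test_standard_zero_beta(self):
        _, p = wald_pvalues(np.array([0.0]), np.array([0.5]), "standard")
        assert p[0] == pytest.approx(1.0)

    def test_standard_symmetry(self):
        _, p_pos = wald_pvalues(np.array([0.7]), np.array([0.2]), "standard")
        _, p_neg = wald_pvalues(np.array([-0.7]), np.array([0.2]), "standard")
        assert p_pos[0] == pytest.approx(p_neg[0])


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestBh:
    def test_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_bruteforce_definition(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


class TestShrinkage:
    def test_tight_se_barely_shrinks(self, rng):
        beta = rng.normal(0, 1, 200)
        se = np.full(200, 1e-4)
        assert np.allclose(shrink_lfc(beta, se), beta, rtol=1e-3)

    def test_huge_se_shrinks_to_zero(self, rng):
        beta = np.concatenate([rng.normal(0, 0.5, 199), [3.0]])
        se = np.concatenate([np.full(199, 0.01), [50.0]])
        assert abs(shrink_lfc(beta, se)[-1]) < 0.01

    def test_magnitude_never_grows(self, rng):
        beta = rng.normal(0, 1, 100)
        se = rng.uniform(0.01, 2, 100)
        assert (np.abs(shrink_lfc(beta, se)) <= np.abs(beta) + 1e-12).all()


class TestOneVsRest:
    def test_power_and_error_control(self):
        lfc = np.zeros(300)
        lfc[:30] = 2.0 / np.log(2)  # beta1 = 2 on the natural-log scale
        counts, _ = simulate_two_condition(300, (3, 6), lfc, dispersion=0.05, mean_count=500, seed=7)
        res = one_vs_rest_lrt(counts, counts.sample_meta["condition"], "treatment")
        assert (res["padj"].iloc[:30] < 0.05).mean() >= 0.95
        assert (res["padj"].iloc[30:] < 0.05).mean() <= 0.05

    def test_permuting_labels_destroys_signal(self, rng):
        lfc = np.zeros(60)
        lfc[0] = 3.0
        counts, _ = simulate_two_condition(60, (3, 6), lfc, dispersion=0.05, mean_count=500, seed=13)
        labels = counts.sample_meta["condition"].to_numpy()
        res = one_vs_rest_lrt(counts, labels, "treatment")
        assert res["p"].iloc[0] < 1e-4
        perm_ps = []
        for _ in range(20):
            perm = rng.permutation(labels)
            if len(set(perm[:3])) == 1:  # degenerate permutation, skip
                continue
            perm_ps.append(one_vs_rest_lrt(counts, perm, "treatment")["p"].iloc[0])
        assert np.median(perm_ps) > 0.1
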