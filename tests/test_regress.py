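"""Regression procedures against independent oracles.

Parametric fits are checked against statsmodels OLS (an independent code
path); permutation tests are checked against exhaustive enumeration of all
permutations on small instances.
"""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from permnet import (
    DegenerateDesignError,
    DyadMatrix,
    InvalidInputError,
    dyad_vector,
    dyadic_ols,
    exact_perm_null,
    from_dyad_vector,
    mmlm_fit,
    node_label_permutation_test,
    ols_nodal,
    qap_test,
    relabel,
)
from permnet.regress import exact_pvalue_two_sided, mmlm_design


def random_sym(rng, n):
    w = rng.random((n, n))
    return DyadMatrix((w + w.T) / 2)


class TestOlsNodal:
    def test_exact_linear_data_recovers_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = ols_nodal(2 * x + 1, x)
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            ols_nodal(np.arange(5.0), np.ones(5))

    def test_matches_statsmodels_on_random_data(self):
        rng = np.random.default_rng(8)
        x = rng.random(20)
        y = 0.4 * x + rng.random(20)
        res = ols_nodal(y, x)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.beta == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(sm_fit.bse[1], abs=1e-10)
        assert res.p == pytest.approx(sm_fit.pvalues[1], abs=1e-10)


class TestNodeLabelPermutation:
    def test_observed_statistic_equals_ols_slope(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(12), rng.random(12)
        res = node_label_permutation_test(y, x, n_perm=50, rng=rng)
        assert res.beta == pytest.approx(ols_nodal(y, x).beta, abs=1e-14)
        assert res.null_sample.shape == (50,)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        x, y = rng.random(5), rng.random(5)
        obs = ols_nodal(y, x).beta
        xc = x - x.mean()
        null = exact_perm_null(lambda p: float(xc @ y[p]) / float(xc @ xc), 5)
        p_exact = exact_pvalue_two_sided(null, obs)
        n_perm = 10_000
        p_mc = node_label_permutation_test(y, x, n_perm=n_perm, rng=rng).p
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * mc_se + 2 / n_perm

    def test_p_is_bounded_below_by_add_one_floor(self):
        x = np.arange(8.0)
        res = node_label_permutation_test(2 * x, x, n_perm=99, rng=np.random.default_rng(0))
        assert 1 / 100 <= res.p <= 1.0


class TestDyadicOls:
    def test_identity_relation(self):
        x = random_sym(np.random.default_rng(11), 8)
        res = dyadic_ols(x, x)
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_gives_zero_slope_p_one(self):
        x = random_sym(np.random.default_rng(12), 6)
        y = from_dyad_vector(6, np.full(15, 3.7))
        res = dyadic_ols(x, y)
        assert res.beta == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_is_degenerate(self):
        y = random_sym(np.random.default_rng(13), 6)
        x = from_dyad_vector(6, np.full(15, 1.0))
        with pytest.raises(DegenerateDesignError):
            dyadic_ols(x, y)

    def test_centring_equals_intercept_regression(self):
        rng = np.random.default_rng(14)
        x, y = random_sym(rng, 6), random_sym(rng, 6)
        res = dyadic_ols(x, y)
        sm_fit = sm.OLS(dyad_vector(y), sm.add_constant(dyad_vector(x))).fit()
        assert res.beta == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert res.p == pytest.approx(sm_fit.pvalues[1], abs=1e-10)


class TestQap:
    def test_reports_the_unadjusted_ols_slope(self):
        rng = np.random.default_rng(15)
        x, y = random_sym(rng, 10), random_sym(rng, 10)
        res = qap_test(x, y, n_perm=20, rng=rng)
        assert res.beta == pytest.approx(dyadic_ols(x, y).beta, abs=1e-14)

    def test_sampled_p_matches_exhaustive_relabelling(self):
        rng = np.random.default_rng(16)
        x, y = random_sym(rng, 4), random_sym(rng, 4)
        obs = dyadic_ols(x, y).beta
        yv = dyad_vector(y)
        yc = yv - yv.mean()

        def stat(perm):
            xv = dyad_vector(relabel(x, perm))
            xc = xv - xv.mean()
            return float(xc @ yc) / float(xc @ xc)

        null = exact_perm_null(stat, 4)
        assert null.size == 24
        p_exact = exact_pvalue_two_sided(null, obs)
        n_perm = 5000
        p_mc = qap_test(x, y, n_perm=n_perm, rng=rng).p
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * mc_se + 2 / n_perm

    def test_relabelling_invariant_input_gives_p_one(self):
        # constant response: every permuted slope is identically zero, so the
        # two-sided permutation p-value is exactly 1
        n = 5
        x = random_sym(np.random.default_rng(22), n)
        y = from_dyad_vector(n, np.full(10, 2.0))
        res = qap_test(x, y, n_perm=50, rng=np.random.default_rng(0))
        assert res.p == 1.0
        assert np.all(res.null_sample == 0.0)

    def test_constant_predictor_matrix_is_degenerate(self):
        n = 5
        x = from_dyad_vector(n, np.ones(10))
        y = random_sym(np.random.default_rng(23), n)
        with pytest.raises(DegenerateDesignError):
            qap_test(x, y, n_perm=10, rng=np.random.default_rng(0))


class TestMmlm:
    def test_response_in_node_effect_span_gives_zero_slope(self):
        rng = np.random.default_rng(17)
        n = 5
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        i, j = np.triu_indices(n, k=1)
        y = from_dyad_vector(n, u[i] + u[j])
        x = random_sym(rng, n)
        fit = mmlm_fit(x, y)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_and_statsmodels(self):
        rng = np.random.default_rng(18)
        x, y = random_sym(rng, 12), random_sym(rng, 12)
        fit = mmlm_fit(x, y)
        a = mmlm_design(x)
        yv = dyad_vector(y)
        coef = np.linalg.solve(a.T @ a, a.T @ yv)
        assert fit.beta == pytest.approx(coef[0], abs=1e-8)
        assert np.allclose(fit.node_effects, coef[1:], atol=1e-8)
        sm_fit = sm.OLS(yv, a).fit()
        assert fit.se_beta == pytest.approx(sm_fit.bse[0], abs=1e-8)
        assert fit.p == pytest.approx(sm_fit.pvalues[0], abs=1e-8)
        assert fit.dof == 66 - 13

    def test_without_node_columns_reduces_to_dyadic_ols(self):
        rng = np.random.default_rng(19)
        x, y = random_sym(rng, 9), random_sym(rng, 9)
        xv, yv = dyad_vector(x), dyad_vector(y)
        slope = np.linalg.lstsq(
            np.column_stack([xv, np.ones_like(xv)]), yv, rcond=None
        )[0][0]
        assert slope == pytest.approx(dyadic_ols(x, y).beta, abs=1e-10)

    def test_rank_deficient_design_is_reported(self):
        n = 5
        x = from_dyad_vector(n, np.ones(10))  # x column inside incidence span
        y = random_sym(np.random.default_rng(20), n)
        with pytest.raises(DegenerateDesignError, match="rank"):
            mmlm_fit(x, y)

    def test_common_relabelling_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(21)
        x, y = random_sym(rng, 8), random_sym(rng, 8)
        p = rng.permutation(8)
        f0, f1 = mmlm_fit(x, y), mmlm_fit(relabel(x, p), relabel(y, p))
        assert f1.beta == pytest.approx(f0.beta, abs=1e-10)
        assert f1.p == pytest.approx(f0.p, abs=1e-10)
        l0, l1 = dyadic_ols(x, y), dyadic_ols(relabel(x, p), relabel(y, p))
        assert l1.beta == pytest.approx(l0.beta, abs=1e-12)


class TestExactEnumeration:
    def test_enumerates_factorial_many_permutations(self):
        null = exact_perm_null(lambda p: float(p[0]), 3)
        assert null.size == 6

    def test_size_above_seven_is_refused(self):
        with pytest.raises(InvalidInputError):
            exact_perm_null(lambda p: 0.0, 8)

    def test_unique_extreme_has_p_one_over_factorial(self):
        # statistic maximised only by the identity permutation
        target = np.arange(4)
        null = exact_perm_null(lambda p: float(np.sum(p == target)), 4)
        obs = 4.0
        assert exact_pvalue_two_sided(null, obs) == pytest.approx(1 / 24)

    def test_every_permutation_visited_once(self):
        seen = set()
        exact_perm_null(lambda p: seen.add(tuple(p.tolist())) or 0.0, 4)
        assert len(seen) == 24
        assert seen == set(itertools.permutations(range(4)))
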