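"""MRQAP: OLS layer, permutation machinery and the DSP test."""

import numpy as np
import pandas as pd
import pytest

import dyadqap as dq
from dyadqap.network_data import ValidationError, offdiag_indices
from dyadqap.qap import draw_permutations, term_pvalues


def random_matrix(n, rng, lo=0.0, hi=1.0, actors=None):
    return dq.DyadicMatrix(actors or [f"a{i}" for i in range(n)],
                           rng.uniform(lo, hi, (n, n)))


class TestOlsDyadic:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 2.0 + 3.0 * x
        fit = dq.ols_dyadic(y, pd.DataFrame({"x": x}))
        assert fit.intercept == pytest.approx(2.0)
        assert fit.estimates["x"] == pytest.approx(3.0)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        fit = dq.ols_dyadic(y, pd.DataFrame({"x": x}))
        se = 1.0 / (np.std(x, ddof=1) * np.sqrt(50))
        assert abs(fit.estimates["x"]) < 3 * se

    def test_standardized_estimate_identity(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"u": rng.normal(size=120), "v": rng.uniform(size=120)})
        y = 1.0 + 0.5 * X["u"] - 2.0 * X["v"] + rng.normal(scale=0.3, size=120)
        fit = dq.ols_dyadic(y.to_numpy(), X)
        for c in X:
            expected = fit.estimates[c] * X[c].std(ddof=1) / y.std(ddof=1)
            assert fit.standardized_estimates[c] == pytest.approx(expected)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=150), "b": rng.normal(size=150)})
        y = 0.7 - 1.2 * X["a"] + 0.4 * X["b"] + rng.normal(scale=0.8, size=150)
        fit = dq.ols_dyadic(y.to_numpy(), X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.intercept == pytest.approx(ref.params["const"])
        assert fit.estimates["a"] == pytest.approx(ref.params["a"])
        assert fit.estimates["b"] == pytest.approx(ref.params["b"])
        assert fit.r2_adj == pytest.approx(ref.rsquared_adj)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        X = pd.DataFrame({"x": x, "x_copy": x})
        with pytest.raises(ValidationError, match="x_copy|x"):
            dq.ols_dyadic(rng.normal(size=60), X)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"c": np.ones(40)})
        with pytest.raises(ValidationError, match="constant"):
            dq.ols_dyadic(rng.normal(size=40), X)


class TestPermutationPvalues:
    def test_lower_bound_and_monotonicity(self):
        null = np.array([-1.0, 0.5, 2.0, -0.3, 1.2])
        # p can never be 0: the observed statistic counts itself
        p_two, _ = term_pvalues(null, 10.0, 0)
        assert p_two == pytest.approx(1 / 6)
        # holding the draws fixed, p is non-increasing in |b_obs|
        ps = [term_pvalues(null, b, 0)[0] for b in (0.1, 0.6, 1.5, 3.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_one_tailed_uses_hypothesized_sign(self):
        null = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        _, p_pos = term_pvalues(null, 1.5, +1)
        _, p_neg = term_pvalues(null, 1.5, -1)
        assert p_pos == pytest.approx(2 / 6)
        assert p_neg == pytest.approx(5 / 6)


class TestDspTest:
    def make_data(self, n=12, seed=0):
        schema = dq.ItemSchema.study1()
        _, S = dq.simulate_strength_network(n, schema, 0.5, seed=seed)
        R = dq.build_reciprocation(S)
        rng = np.random.default_rng(seed + 1)
        Yv = 2.0 + 4.0 * S.values + rng.normal(scale=1.5, size=(n, n))
        Y = dq.DyadicMatrix(S.actors, Yv, kind="allocation")
        return Y, {"strength": S, "reciprocation": R}

    def test_point_estimates_equal_ols_regardless_of_n_perm(self):
        Y, X = self.make_data()
        r, c = offdiag_indices(Y.n)
        fits = [dq.dsp_test(Y, X, dq.PermutationPlan(n, seed=7)) for n in (10, 100)]
        ref = dq.ols_dyadic(
            Y.values[r, c],
            pd.DataFrame({k: v.values[r, c] for k, v in X.items()}),
        )
        for res in fits:
            for t in res.terms:
                assert t.estimate == pytest.approx(ref.estimates[t.term], abs=1e-12)
            assert res.r2_adj == pytest.approx(ref.r2_adj)

    def test_same_seed_reproduces(self):
        Y, X = self.make_data()
        r1 = dq.dsp_test(Y, X, dq.PermutationPlan(200, seed=11))
        r2 = dq.dsp_test(Y, X, dq.PermutationPlan(200, seed=11))
        assert [t.p_two_tailed for t in r1.terms] == [t.p_two_tailed for t in r2.terms]
        assert r1.model_p == r2.model_p

    def test_estimates_invariant_under_actor_relabeling(self):
        Y, X = self.make_data()
        rng = np.random.default_rng(13)
        pi = rng.permutation(Y.n)
        Yp = dq.permute_square(Y, pi)
        Xp = {k: dq.permute_square(v, pi) for k, v in X.items()}
        a = dq.dsp_test(Y, X, dq.PermutationPlan(10, seed=1))
        b = dq.dsp_test(Yp, Xp, dq.PermutationPlan(10, seed=1))
        for ta, tb in zip(a.terms, b.terms):
            assert ta.estimate == pytest.approx(tb.estimate, abs=1e-10)

    def test_matches_naive_loop_implementation(self):
        """The batched permutation engine must agree exactly with a naive
        per-permutation loop built from permute_square and lstsq."""
        Y, X = self.make_data(n=8, seed=5)
        n_perm, seed = 60, 21
        res = dq.dsp_test(Y, X, dq.PermutationPlan(n_perm, seed=seed))

        n = Y.n
        r, c = offdiag_indices(n)
        y = Y.values[r, c]
        names = list(X)
        cols = {k: v.values[r, c] for k, v in X.items()}
        perms = draw_permutations(n, n_perm, np.random.default_rng(seed))
        for k, nm in enumerate(names):
            others = [o for o in names if o != nm]
            Z = np.column_stack([np.ones(len(y))] + [cols[o] for o in others])
            gamma, *_ = np.linalg.lstsq(Z, cols[nm], rcond=None)
            e = cols[nm] - Z @ gamma
            E = np.zeros((n, n))
            E[r, c] = e
            Emat = dq.DyadicMatrix(Y.actors, E)
            null = []
            for p in range(n_perm):
                ep = dq.permute_square(Emat, perms[p]).values[r, c]
                D = np.column_stack([Z, ep])
                beta, *_ = np.linalg.lstsq(D, y, rcond=None)
                null.append(beta[-1])
            null = np.asarray(null)
            b_obs = res.term(nm).estimate
            p_two = (1 + (np.abs(null) >= abs(b_obs)).sum()) / (n_perm + 1)
            assert res.term(nm).p_two_tailed == pytest.approx(p_two, abs=1e-12)

    def test_single_predictor_dsp_agrees_with_qap_y(self):
        """For one predictor the DSP and outcome-permutation nulls coincide
        (the slope is a permutation-invariant bilinear form), so their
        p-values differ only by Monte-Carlo error."""
        rng = np.random.default_rng(17)
        for rep in range(6):
            n = 14
            S = random_matrix(n, rng)
            Y = random_matrix(n, rng, 0, 5)
            res = dq.dsp_test(Y, {"s": S}, dq.PermutationPlan(2000, seed=rep))
            # naive QAP-Y: permute the outcome matrix instead
            r, c = offdiag_indices(n)
            y, x = Y.values[r, c], S.values[r, c]
            b_obs = res.term("s").estimate
            perms = draw_permutations(n, 2000, np.random.default_rng(900 + rep))
            null = []
            for p in range(2000):
                yp = Y.values[np.ix_(perms[p], perms[p])][r, c]
                null.append(np.polyfit(x, yp, 1)[0])
            p_qapy = (1 + (np.abs(null) >= abs(b_obs)).sum()) / 2001
            assert res.term("s").p_two_tailed == pytest.approx(p_qapy, abs=0.05)

    def test_recovery_at_published_effect_size(self):
        # outcome built as 4.84 x strength + small noise in a 23-actor
        # classroom: the strength term must be detected and recovered
        schema = dq.ItemSchema.study1()
        _, S = dq.simulate_strength_network(23, schema, 0.5, seed=9)
        rng = np.random.default_rng(10)
        Yv = 2.0 + 4.84 * S.values + rng.normal(scale=0.5, size=(23, 23))
        Y = dq.DyadicMatrix(S.actors, Yv, kind="allocation")
        R = dq.build_reciprocation(S)
        res = dq.dsp_test(Y, {"strength": S, "reciprocation": R},
                          dq.PermutationPlan(1000, seed=2),
                          {"strength": +1})
        t = res.term("strength")
        assert t.p_one_tailed < 0.01
        assert t.estimate == pytest.approx(4.84, rel=0.10)

    def test_duplicate_predictor_rank_error(self):
        Y, X = self.make_data()
        X2 = dict(X)
        X2["strength_copy"] = X["strength"]
        with pytest.raises(ValidationError, match="rank deficient"):
            dq.dsp_test(Y, X2, dq.PermutationPlan(10, seed=0))

    def test_listwise_missing_dyads_dropped_with_count(self):
        Y, X = self.make_data()
        Yv = Y.values.copy()
        Yv[0, 1] = np.nan
        Yv[2, 3] = np.nan
        Y2 = dq.DyadicMatrix(Y.actors, Yv, kind="allocation")
        res = dq.dsp_test(Y2, X, dq.PermutationPlan(10, seed=0))
        assert res.n_dropped == 2
        assert res.n_dyads == Y.n * (Y.n - 1) - 2
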