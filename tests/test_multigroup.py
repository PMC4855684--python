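"""Pooled multigroup MRQAP: design, estimates and restricted permutations."""

import numpy as np
import pandas as pd
import pytest

import dyadqap as dq
from dyadqap.multigroup import build_design, interaction_name
from dyadqap.network_data import ValidationError, offdiag_indices


def make_group(gid, n, code, seed, betas=None, noise=1.0, intercept=2.0):
    schema = dq.ItemSchema.study1()
    actors = [f"{gid}_{i}" for i in range(n)]
    _, S = dq.simulate_strength_network(n, schema, 0.5, seed, actors=actors)
    R = dq.build_reciprocation(S)
    rng = np.random.default_rng(seed + 1)
    betas = betas or {}
    Yv = (intercept + betas.get("strength", 0.0) * S.values
          + betas.get("reciprocation", 0.0) * R.values
          + rng.normal(scale=noise, size=(n, n)))
    Y = dq.DyadicMatrix(actors, Yv, kind="allocation")
    return dq.GroupData(
        group_id=gid,
        actors=pd.DataFrame({"actor_id": actors, "group_id": gid}),
        Y=Y,
        predictors={"strength": S, "reciprocation": R},
        group_code=code,
    )


class TestInteractionMatrix:
    @pytest.mark.parametrize("code, factor", [(0, 0.0), (1, 1.0), (2, 2.0)])
    def test_code_scaling(self, small_strength, code, factor):
        M = dq.build_interaction_matrix(small_strength, code)
        assert np.allclose(M.values, small_strength.values * factor, equal_nan=True)


class TestDesign:
    def test_intercept_dummies_and_interaction_columns(self):
        g0 = make_group("g0", 6, 0, seed=1)
        g1 = make_group("g1", 5, 1, seed=2)
        design = build_design([g0, g1], ["strength", "reciprocation"],
                              ["reciprocation"])
        assert design.column_names[:2] == ["intercept[g0]", "intercept[g1]"]
        assert design.column_names[-1] == interaction_name("reciprocation")
        # interaction column is predictor x group code: zero in the
        # reference group, equal to the predictor in the code-1 group
        sl0, sl1 = design.group_slices
        recip = design.column_names.index("reciprocation")
        inter = design.column_names.index(interaction_name("reciprocation"))
        assert np.all(design.D[sl0, inter] == 0.0)
        assert np.allclose(design.D[sl1, inter], design.D[sl1, recip])

    def test_unknown_interaction_rejected(self):
        g0 = make_group("g0", 5, 0, seed=3)
        g1 = make_group("g1", 5, 1, seed=4)
        with pytest.raises(ValidationError, match="not in the model"):
            build_design([g0, g1], ["strength"], ["reciprocation"])

    def test_tiny_group_rejected(self):
        g0 = make_group("g0", 5, 0, seed=5)
        with pytest.raises(ValidationError, match="at least 3"):
            g_bad = make_group("gx", 3, 1, seed=6)
            g_bad = dq.GroupData(
                group_id="gx",
                actors=g_bad.actors.iloc[:2],
                Y=dq.DyadicMatrix(g_bad.Y.actors[:2], g_bad.Y.values[:2, :2]),
                predictors={k: dq.DyadicMatrix(v.actors[:2], v.values[:2, :2])
                            for k, v in g_bad.predictors.items()},
                group_code=1,
            )
            build_design([g0, g_bad], ["strength"])


class TestEstimates:
    def test_single_group_equals_single_network_mrqap(self):
        g = make_group("g0", 10, 0, seed=7, betas={"strength": 3.0}, noise=1.0)
        mg = dq.mg_fit([g], ["strength", "reciprocation"],
                       plan=dq.PermutationPlan(10, seed=1))
        r, c = offdiag_indices(g.n)
        ref = dq.ols_dyadic(
            g.Y.values[r, c],
            pd.DataFrame({k: v.values[r, c] for k, v in g.predictors.items()}),
        )
        assert mg.term("strength").estimate == pytest.approx(ref.estimates["strength"], abs=1e-10)
        assert mg.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert mg.r2_adj == pytest.approx(ref.r2_adj)

    def test_matches_statsmodels_on_stacked_design(self):
        import statsmodels.api as sm

        g0 = make_group("g0", 8, 0, seed=8, betas={"strength": 2.0})
        g1 = make_group("g1", 7, 1, seed=9, betas={"strength": 2.0})
        design = build_design([g0, g1], ["strength", "reciprocation"], ["reciprocation"])
        mg = dq.mg_fit([g0, g1], ["strength", "reciprocation"], ["reciprocation"],
                       dq.PermutationPlan(10, seed=2))
        ref = sm.OLS(design.y, design.D).fit()
        for j, nm in enumerate(design.column_names):
            assert mg.term(nm).estimate == pytest.approx(ref.params[j], abs=1e-10)
        assert mg.r2_adj == pytest.approx(ref.rsquared_adj)

    def test_invariant_to_group_order_and_relabeling(self):
        g0 = make_group("g0", 8, 0, seed=10, betas={"strength": 2.0})
        g1 = make_group("g1", 7, 1, seed=11, betas={"strength": 2.0})
        a = dq.mg_fit([g0, g1], ["strength"], plan=dq.PermutationPlan(10, seed=3))
        # relabel actors within g1
        rng = np.random.default_rng(12)
        pi = rng.permutation(g1.n)
        g1r = dq.GroupData(
            group_id="g1",
            actors=g1.actors.iloc[pi].reset_index(drop=True),
            Y=dq.DyadicMatrix([g1.Y.actors[i] for i in pi],
                              g1.Y.values[np.ix_(pi, pi)], kind="allocation"),
            predictors={k: dq.DyadicMatrix([v.actors[i] for i in pi],
                                           v.values[np.ix_(pi, pi)])
                        for k, v in g1.predictors.items()},
            group_code=1,
        )
        b = dq.mg_fit([g0, g1r], ["strength"], plan=dq.PermutationPlan(10, seed=3))
        assert a.term("strength").estimate == pytest.approx(b.term("strength").estimate, abs=1e-10)
        # swapped order changes the reference group but not the slope
        c = dq.mg_fit([g1, g0], ["strength"], plan=dq.PermutationPlan(10, seed=3))
        assert c.term("strength").estimate == pytest.approx(a.term("strength").estimate, abs=1e-10)

    def test_identical_group_codes_trigger_rank_error(self):
        g0 = make_group("g0", 7, 1, seed=13)
        g1 = make_group("g1", 7, 1, seed=14)
        with pytest.raises(ValidationError, match="rank deficient"):
            dq.mg_fit([g0, g1], ["strength"], ["strength"],
                      dq.PermutationPlan(10, seed=0))

    def test_all_zero_codes_reproduce_common_slope_model(self):
        # brute-force check on 4+4 actors: with every code 0 (and no
        # interactions) the fit is a common-slope model with per-group
        # intercepts on the concatenated dyad table
        g0 = make_group("g0", 4, 0, seed=15, betas={"strength": 2.5}, noise=0.5)
        g1 = make_group("g1", 4, 0, seed=16, betas={"strength": 2.5}, noise=0.5)
        mg = dq.mg_fit([g0, g1], ["strength"], plan=dq.PermutationPlan(10, seed=4))
        rows = []
        for g, dummy in ((g0, 0.0), (g1, 1.0)):
            r, c = offdiag_indices(g.n)
            for y, x in zip(g.Y.values[r, c], g.predictors["strength"].values[r, c]):
                rows.append((1.0, dummy, x, y))
        A = np.array([(a, b, x) for a, b, x, _ in rows])
        yv = np.array([y for *_, y in rows])
        beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
        assert mg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert mg.term("intercept[g1]").estimate == pytest.approx(beta[1], abs=1e-10)
        assert mg.term("strength").estimate == pytest.approx(beta[2], abs=1e-10)


class TestInference:
    def test_interaction_recovery_low_noise(self):
        # reciprocation slope 0 in the code-0 group and 2.64 in the code-1
        # group: the interaction term recovers the difference
        g0 = make_group("g0", 12, 0, seed=17, betas={"strength": 3.0}, noise=0.5)
        g1 = make_group("g1", 11, 1, seed=18,
                        betas={"strength": 3.0, "reciprocation": 2.64}, noise=0.5)
        res = dq.mg_fit([g0, g1], ["strength", "reciprocation"], ["reciprocation"],
                        dq.PermutationPlan(2000, seed=5),
                        {interaction_name("reciprocation"): +1})
        t = res.term(interaction_name("reciprocation"))
        assert t.estimate == pytest.approx(2.64, rel=0.15)
        assert t.p_one_tailed < 0.05

    def test_dsp_variant_runs_and_agrees_on_strong_effect(self):
        g0 = make_group("g0", 10, 0, seed=19, betas={"strength": 4.0}, noise=0.8)
        g1 = make_group("g1", 9, 1, seed=20, betas={"strength": 4.0}, noise=0.8)
        for method in ("qap_y", "dsp"):
            res = dq.mg_fit([g0, g1], ["strength", "reciprocation"],
                            plan=dq.PermutationPlan(500, seed=6), method=method)
            assert res.term("strength").p_two_tailed < 0.05

    def test_standardized_estimates_absent(self):
        g0 = make_group("g0", 8, 0, seed=21)
        g1 = make_group("g1", 7, 1, seed=22)
        res = dq.mg_fit([g0, g1], ["strength"], plan=dq.PermutationPlan(10, seed=7))
        assert all(t.standardized_estimate is None for t in res.terms)

    def test_same_seed_reproduces(self):
        g0 = make_group("g0", 8, 0, seed=23, betas={"strength": 2.0})
        g1 = make_group("g1", 7, 1, seed=24, betas={"strength": 2.0})
        r1 = dq.mg_fit([g0, g1], ["strength"], plan=dq.PermutationPlan(300, seed=8))
        r2 = dq.mg_fit([g0, g1], ["strength"], plan=dq.PermutationPlan(300, seed=8))
        assert [t.p_two_tailed for t in r1.terms] == [t.p_two_tailed for t in r2.terms]
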