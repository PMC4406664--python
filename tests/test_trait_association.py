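"""OLS association machinery, FDR, KW, permutation and residual scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import phyloexpr as px
from phyloexpr.trait_association import AssociationError, _kw_many


class TestRelativeLogTrait:
    def test_powers_of_two(self):
        np.testing.assert_allclose(px.relative_log_trait([2, 4, 8]), [0, 1, 2])

    def test_constant(self):
        np.testing.assert_allclose(px.relative_log_trait([5, 5, 5]), 0.0)

    def test_hand_value(self):
        np.testing.assert_allclose(px.relative_log_trait([3, 7]),
                                   [0.0, np.log2(7 / 3)], atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(AssociationError):
            px.relative_log_trait([1.0, 0.0])


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = px.ols_fit(2 * x, x)
        assert fit.coef[1] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_covariance_slope(self):
        x = np.array([-2.0, -1, 1, 2, 0])
        y = np.array([1.0, 1, 1, 1, 5])  # orthogonal to x
        fit = px.ols_fit(y, x)
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-12)

    def test_f_p_matches_statsmodels(self):
        import statsmodels.api as sm
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        fit = px.ols_fit(y, x)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.p == pytest.approx(sm_fit.f_pvalue, abs=1e-10)
        assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(6.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(AssociationError, match="collinear"):
            px.ols_fit(np.ones(6), X, names=["t", "t_copy"])

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(0)
        fit = px.ols_fit(rng.normal(size=20), rng.normal(size=20))
        assert abs(fit.residuals.sum()) < 1e-9


class TestTraitPairRegression:
    def test_power_law_r2_one(self):
        w = np.array([10.0, 100, 1000, 5000, 20000])
        t = w ** 0.25
        r2, p, _ = px.trait_pair_regression(np.log2(w), np.log2(t))
        assert r2 == pytest.approx(1.0)

    def test_permuted_trait_near_zero_r2(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = rng.permutation(rng.normal(size=500))
        r2, p, _ = px.trait_pair_regression(x, y)
        assert r2 < 0.05

    def test_three_collinear_points(self):
        r2, p, line = px.trait_pair_regression(
            np.array([0.0, 1, 2]), np.array([1.0, 3, 5]))
        assert r2 == pytest.approx(1.0)
        assert np.isfinite(p)


class TestAllometricResiduals:
    def test_exact_power_law_zero_residuals(self):
        w = np.array([10.0, 100, 1000, 5000])
        resid, (b0, b1) = px.allometric_residuals(w ** 0.25, w)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)
        assert b1 == pytest.approx(0.25)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(2)
        w = rng.lognormal(5, 2, size=30)
        t = rng.lognormal(2, 1, size=30)
        resid, _ = px.allometric_residuals(t, w)
        assert abs(resid.sum()) < 1e-9

    def test_planted_offsets_recovered(self):
        rng = np.random.default_rng(3)
        w = rng.lognormal(5, 2, size=40)
        offsets = rng.normal(0, 1, size=40)
        t = np.power(2.0, 0.3 * np.log2(w) + offsets)
        resid, _ = px.allometric_residuals(t, w)
        assert np.corrcoef(resid, offsets)[0, 1] >= 0.99


class TestBhFdr:
    def test_hand_step_up(self):
        q = px.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, 0.05)

    def test_single_p(self):
        assert px.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_ones(self):
        np.testing.assert_allclose(px.bh_fdr(np.ones(10)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(AssociationError):
            px.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30))
    def test_monotone_and_permutation_invariant(self, pvals):
        p = np.array(pvals)
        q = px.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(px.bh_fdr(p[perm]), q[perm], atol=1e-12)


class TestKruskalWallis:
    def test_hand_rank_formula(self):
        H, p = px.kw_test([[1, 2, 3], [4, 5, 6]])
        assert H == pytest.approx(3.857, abs=1e-3)

    def test_all_equal(self):
        H, p = px.kw_test([[2, 2], [2, 2]])
        assert H == 0.0 and p == 1.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            v = rng.normal(size=9)
            ps.append(px.kw_test([v[:3], v[3:6], v[6:]])[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_vectorized_matches_scipy(self):
        rng = np.random.default_rng(5)
        codes = np.repeat(np.arange(5), 3)
        vals = rng.normal(size=(50, 15))
        vals[:10] = np.round(vals[:10], 1)  # force ties in some rows
        H, p = _kw_many(vals, codes, 5)
        for i in range(50):
            ref = stats.kruskal(*[vals[i, codes == k] for k in range(5)])
            assert H[i] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-8)


class TestPermutationPvalue:
    def test_minimum_attainable(self):
        x = np.arange(10.0)
        p = px.permutation_pvalue(2 * x, x, n_reps=99, seed=0)
        assert p >= 1 / 100
        assert p == pytest.approx(1 / 100)

    def test_constant_response(self):
        assert px.permutation_pvalue(np.ones(8), np.arange(8.0), 50, 0) == 1.0

    def test_agrees_with_parametric_under_gaussian_null(self):
        rng = np.random.default_rng(6)
        n_reps = 20_000
        for _ in range(5):
            y = rng.normal(size=20)
            x = rng.normal(size=20)
            p_f = px.ols_fit(y, x).p
            p_perm = px.permutation_pvalue(y, x, n_reps, rng)
            se = np.sqrt(p_f * (1 - p_f) / n_reps)
            assert abs(p_perm - p_f) <= 4 * se + 2 / n_reps


@pytest.fixture(scope="module")
def planted_organ(tree33_mod, traits33_mod):
    # stable-class background: the F-test's null model (exchangeable
    # errors) holds, so FDP against ground truth is interpretable
    cfg = px.SimulationConfig(seed=7, n_genes=1500, frac_drift=0.0,
                              frac_stable=0.90,
                              linked_traits=("maturity_days",))
    m, sheet_df, gt = px.simulate_expression(
        tree33_mod, traits33_mod, cfg, seed=np.random.default_rng(70))
    sheet = px.SampleSheet(sheet_df)
    rel = px.species_relative_expression(px.filter_fpkm(m, sheet), sheet)
    return rel, gt


@pytest.fixture(scope="module")
def tree33_mod():
    return px.simulate_tree(33, seed=11)


@pytest.fixture(scope="module")
def traits33_mod(tree33_mod):
    cfg = px.SimulationConfig(seed=11)
    return px.simulate_traits(tree33_mod, cfg,
                              seed=np.random.default_rng(21))[0]


class TestAssociate:
    def test_planted_recovery(self, planted_organ, traits33_mod):
        rel, gt = planted_organ
        res = px.associate(rel, traits33_mod, "maturity_days")
        truth = gt.set_index("gene").loc[res["gene"]]
        linked = (truth["gene_class"] == "trait_linked").to_numpy()
        hits = res["associated"].to_numpy()
        sensitivity = hits[linked].mean()
        fdp = (hits & ~linked).sum() / max(hits.sum(), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.10

    def test_perfect_gene_has_smallest_p(self, traits33_mod, tree33_mod):
        x = px.relative_log_trait(
            traits33_mod["max_lifespan_years"].to_numpy())
        rng = np.random.default_rng(8)
        species = list(traits33_mod.index)
        genes = [f"g{i}" for i in range(50)]
        Y = rng.normal(size=(50, 33))
        Y[0] = 2.0 * x + 1.0  # exact linear relation
        sm = pd.DataFrame(Y, index=genes, columns=species)
        sheet = px.SampleSheet(pd.DataFrame({
            "sample_id": species, "species": species,
            "organ": "liver", "replicate": 1}))
        rel = px.RelativeExpression(sm, sm.copy().set_axis(species, axis=1),
                                    sheet)
        res = px.associate(rel, traits33_mod, "max_lifespan_years")
        assert res.loc[res["f_p"].idxmin(), "gene"] == "g0"
        assert res.loc[0, "slope"] == pytest.approx(2.0, abs=1e-6)

    def test_requires_species_overlap(self, planted_organ):
        rel, _ = planted_organ
        tiny = pd.DataFrame({"maturity_days": [1.0, 2.0]},
                            index=["sp01", "sp02"])
        with pytest.raises(AssociationError, match="species"):
            px.associate(rel, tiny, "maturity_days")

    def test_missing_trait_column(self, planted_organ, traits33_mod):
        rel, _ = planted_organ
        with pytest.raises(AssociationError, match="not found"):
            px.associate(rel, traits33_mod, "no_such_trait")

    def test_null_discoveries_controlled(self, tree33_mod, traits33_mod):
        cfg = px.SimulationConfig(seed=9, n_genes=1000, frac_trait_linked=0.0,
                                  frac_drift=0.0, frac_stable=1.0)
        fdps = []
        for r in range(10):
            m, sheet_df, _ = px.simulate_expression(
                tree33_mod, traits33_mod, cfg,
                seed=np.random.default_rng(900 + r))
            sheet = px.SampleSheet(sheet_df)
            rel = px.species_relative_expression(
                px.filter_fpkm(m, sheet), sheet)
            res = px.associate(rel, traits33_mod, "maturity_days")
            fdps.append(1.0 if res["associated"].any() else 0.0)
        assert np.mean(fdps) <= 0.2  # generous at 10 runs; FDR target 0.05


class TestResidualInteractionScan:
    def test_detects_residual_not_weight(self, traits33_mod):
        # genes driven by allometric residuals of maturity are detected;
        # genes driven purely by body weight are not
        species = list(traits33_mod.index)
        t = traits33_mod["maturity_days"].to_numpy(float)
        w = traits33_mod["adult_weight_g"].to_numpy(float)
        resid, _ = px.allometric_residuals(t, w)
        rng = np.random.default_rng(10)
        n_each = 60
        Y = np.vstack([
            3.0 * resid + rng.normal(0, 0.3, size=(n_each, 33)),
            1.0 * px.relative_log_trait(w) + rng.normal(0, 0.3, size=(n_each, 33)),
        ])
        genes = [f"res{i}" for i in range(n_each)] + [f"wt{i}" for i in range(n_each)]
        sm = pd.DataFrame(Y, index=genes, columns=species)
        sheet = px.SampleSheet(pd.DataFrame({
            "sample_id": species, "species": species, "organ": "liver",
            "replicate": 1}))
        rel = px.RelativeExpression(sm, sm.copy(), sheet)
        out = px.residual_interaction_scan(rel, traits33_mod, "maturity_days")
        hits = out.set_index("gene")["significant"]
        sens = hits[[f"res{i}" for i in range(n_each)]].mean()
        spec = 1.0 - hits[[f"wt{i}" for i in range(n_each)]].mean()
        assert sens >= 0.8
        assert spec >= 0.95

    def test_collinear_trait_weight_rejected(self, traits33_mod):
        species = list(traits33_mod.index)
        bad = traits33_mod.copy()
        bad["maturity_days"] = bad["adult_weight_g"]
        sm = pd.DataFrame(np.ones((3, 33)), columns=species,
                          index=["a", "b", "c"])
        sheet = px.SampleSheet(pd.DataFrame({
            "sample_id": species, "species": species, "organ": "o",
            "replicate": 1}))
        rel = px.RelativeExpression(sm, sm.copy(), sheet)
        with pytest.raises(AssociationError, match="rank deficient"):
            px.residual_interaction_scan(rel, bad, "maturity_days")

    def test_null_partial_f_uniform(self, traits33_mod):
        species = list(traits33_mod.index)
        rng = np.random.default_rng(11)
        sm = pd.DataFrame(rng.normal(size=(2000, 33)), columns=species)
        sheet = px.SampleSheet(pd.DataFrame({
            "sample_id": species, "species": species, "organ": "o",
            "replicate": 1}))
        rel = px.RelativeExpression(sm, sm.copy(), sheet)
        out = px.residual_interaction_scan(rel, traits33_mod, "maturity_days")
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestSummarizeCounts:
    def test_shared_genes_overlap(self):
        sets = {("liver", "t1"): {"a", "b", "c", "d", "e", "f"},
                ("liver", "t2"): {"b", "c", "d", "e", "f", "g"}}
        out = px.summarize_counts(sets, {"liver": 100})
        row = out.set_index("trait").loc["t1"]
        assert row["liver_n"] == 6
        assert row["liver_specific"] == 1  # only "a" is t1-specific

    def test_disjoint_traits_all_specific(self):
        sets = {("liver", "t1"): {"a", "b"}, ("liver", "t2"): {"c"}}
        out = px.summarize_counts(sets, {"liver": 10}).set_index("trait")
        assert out.loc["t1", "liver_specific"] == 2
        assert out.loc["combined", "liver_n"] == 3

    def test_random_labels_match_brute_force(self):
        rng = np.random.default_rng(12)
        organs, traits = ["liver", "brain"], ["t1", "t2", "t3"]
        genes = [f"g{i}" for i in range(40)]
        sets = {(o, t): set(rng.choice(genes, size=15, replace=False))
                for o in organs for t in traits}
        out = px.summarize_counts(sets, {o: 40 for o in organs}).set_index("trait")
        for t in traits:
            union = sets[("liver", t)] | sets[("brain", t)]
            inter = sets[("liver", t)] & sets[("brain", t)]
            assert out.loc[t, "combined_n"] == len(union)
            assert out.loc[t, "combined_overlap"] == len(inter)
            for o in organs:
                others = set().union(*(sets[(o, t2)] for t2 in traits if t2 != t))
                assert out.loc[t, f"{o}_specific"] == len(sets[(o, t)] - others)
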