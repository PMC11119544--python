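"""Phylogenetic mixed model: likelihood, fitting, partition, selection,
importance, and partial effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodens import pmm
from phylodens import synthetic as syn
from phylodens import treekit as tk


def zero_beta():
    return {k: 0.0 for k in syn.DEFAULT_BETA}


def recovery_sim(seed, n_species=150, s2p=0.8, s2s=0.15, s2e=0.05, beta=None,
                 sites=3):
    cfg = syn.SimConfig(n_species=n_species, lam=1.0, sigma2_p=s2p,
                        sigma2_s=s2s, sigma2_e=s2e, intercept=0.0,
                        beta=beta or zero_beta(), sites_per_species=sites,
                        ensure_positive=False, seed=seed)
    return syn.simulate_table(cfg)


class TestBuildDesign:
    def test_lambda_is_unit_diagonal_correlation(self):
        tree = tk.read_newick("((A:1,B:1):1,C:2);")
        table = pd.DataFrame({
            "species": ["A", "B", "C", "A"],
            "wood_density": [0.4, 0.5, 0.6, 0.45],
            "mat": [1.0, 2.0, 3.0, 4.0],
        })
        d = pmm.build_design(table, tree, ["mat"])
        assert d.species_labels == ("A", "B", "C")
        assert np.allclose(d.Lambda, [[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]])

    def test_missing_species_dropped_and_counted(self):
        tree = tk.read_newick("((A:1,B:1):1,C:2);")
        table = pd.DataFrame({
            "species": ["A", "B", "D", "A"],
            "wood_density": [0.4, 0.5, 0.6, 0.45],
        })
        d = pmm.build_design(table, tree, [])
        assert d.n_dropped == 1 and d.n_rows == 3

    def test_empty_intersection_raises(self):
        tree = tk.read_newick("(A:1,B:1);")
        table = pd.DataFrame({"species": ["X"], "wood_density": [0.5]})
        with pytest.raises(ValueError, match="no species shared"):
            pmm.build_design(table, tree, [])

    def test_intercept_only_design(self):
        sim = recovery_sim(0, n_species=10)
        d = pmm.build_design(sim.table, sim.tree, [])
        assert d.X.shape[1] == 1 and d.fixed_names == ("intercept",)


class TestMarginalLoglik:
    def test_matches_dense_oracle(self):
        """Woodbury path equals brute-force MVN log-density on a toy design."""
        sim = recovery_sim(1, n_species=8, sites=3)
        d = pmm.build_design(sim.table, sim.tree, ["mat", "map"])
        Z = np.zeros((d.n_rows, d.n_species))
        Z[np.arange(d.n_rows), d.codes] = 1.0
        beta0 = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        rng = np.random.default_rng(2)
        for _ in range(20):
            s2p, s2s, s2e = rng.uniform(0.05, 2.0, 3)
            beta = beta0 + rng.normal(0, 0.1, beta0.size)
            got = pmm.marginal_loglik(d, s2p, s2s, s2e, beta=beta)
            V = s2p * Z @ d.Lambda @ Z.T + s2s * Z @ Z.T + s2e * np.eye(d.n_rows)
            r = d.y - d.X @ beta
            _, logdet = np.linalg.slogdet(V)
            expect = -0.5 * (d.n_rows * np.log(2 * np.pi) + logdet
                             + r @ np.linalg.solve(V, r))
            assert got == pytest.approx(expect, abs=1e-8)

    def test_profiled_beta_dominates(self):
        sim = recovery_sim(3, n_species=20)
        d = pmm.build_design(sim.table, sim.tree, ["mat"])
        rng = np.random.default_rng(4)
        ll_prof = pmm.marginal_loglik(d, 0.5, 0.1, 0.1)
        for _ in range(5):
            beta = rng.normal(0, 0.3, d.X.shape[1])
            assert ll_prof >= pmm.marginal_loglik(d, 0.5, 0.1, 0.1,
                                                  beta=beta) - 1e-9


class TestVariancePartition:
    @pytest.mark.parametrize("comp,expect", [
        ((0.0, 1.0, 0.0, 0.0), {"R2p": 1.0, "R2s": 0.0, "R2c": 1.0, "R2m": 0.0}),
        ((1.0, 0.0, 0.0, 1.0), {"R2p": 0.0, "R2s": 0.0, "R2c": 0.5, "R2m": 0.5}),
    ])
    def test_arithmetic_cases(self, comp, expect):
        got = pmm.variance_partition(*comp)
        for key, val in expect.items():
            assert got[key] == pytest.approx(val)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.floats(0, 10, allow_nan=False)] * 4)
           .filter(lambda t: sum(t) > 1e-6),
           st.floats(0.1, 100, allow_nan=False))
    def test_scale_invariance_and_bounds(self, comps, k):
        a = pmm.variance_partition(*comps)
        b = pmm.variance_partition(*[c * k for c in comps])
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9, abs=1e-12)
            assert 0.0 <= a[key] <= 1.0
        s2f, s2p, s2s, s2e = comps
        total = sum(comps)
        assert a["R2p"] + a["R2s"] + s2f / total + s2e / total == pytest.approx(
            1.0, abs=1e-12)
        assert a["R2p"] + a["R2s"] <= a["R2c"] + 1e-12

    def test_no_fixed_effects_r2m_zero_r2c_additive(self):
        got = pmm.variance_partition(0.0, 0.4, 0.3, 0.3)
        assert got["R2m"] == 0.0
        assert got["R2c"] == pytest.approx(got["R2p"] + got["R2s"])

    def test_residual_convention(self):
        got = pmm.variance_partition(1.0, 2.0, 0.0, 1.0,
                                     r2m_convention="residual")
        assert got["R2m"] == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pmm.variance_partition(0, 0, 0, 0)


class TestFitML:
    def test_recovery_single_rep(self):
        sim = recovery_sim(10, n_species=250)
        d = pmm.build_design(sim.table, sim.tree, [])
        fit = pmm.fit_pmm_ml(d)
        assert fit.partition["R2p"] == pytest.approx(0.8, abs=0.15)
        assert fit.sigma2_e == pytest.approx(0.05, rel=0.5)

    def test_degenerate_truth_matches_ols(self):
        cfg = syn.SimConfig(n_species=120, sigma2_p=0.0, sigma2_s=0.0,
                            sigma2_e=0.3, intercept=0.0,
                            beta={**zero_beta(), "mat": 0.01},
                            ensure_positive=False, seed=11)
        sim = syn.simulate_table(cfg)
        d = pmm.build_design(sim.table, sim.tree, ["mat"])
        fit = pmm.fit_pmm_ml(d)
        assert fit.partition["R2p"] <= 0.05
        assert fit.partition["R2s"] <= 0.05
        import statsmodels.api as sm

        ols = sm.OLS(d.y, d.X).fit()
        assert np.allclose(fit.beta["estimate"].to_numpy(), ols.params,
                           atol=1e-3)

    def test_reml_close_to_ml_at_scale(self):
        sim = recovery_sim(12, n_species=100)
        d = pmm.build_design(sim.table, sim.tree, [])
        ml = pmm.fit_pmm_ml(d)
        reml = pmm.fit_pmm_ml(d, reml=True)
        assert reml.partition["R2p"] == pytest.approx(ml.partition["R2p"],
                                                      abs=0.05)

    def test_identity_lambda_reported_unidentifiable(self):
        """With Lambda = I the phylogeny/species split is not estimable."""
        tree = tk.read_newick("(A:1,B:1,C:1,D:1);")  # star: Lambda == I
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "species": list("ABCD") * 3,
            "wood_density": rng.normal(0.5, 0.1, 12),
        })
        d = pmm.build_design(table, tree, [])
        fit = pmm.fit_pmm_ml(d)
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_single_row_per_species_rejected(self):
        sim = recovery_sim(13, n_species=20, sites=1)
        d = pmm.build_design(sim.table, sim.tree, [])
        with pytest.raises(pmm.NotIdentifiableError, match="aggregate"):
            pmm.fit_pmm_ml(d)


@pytest.fixture(scope="module")
def mcmc_fit():
    sim = recovery_sim(20, n_species=100)
    d = pmm.build_design(sim.table, sim.tree, [])
    return pmm.fit_pmm_mcmc(d, n_iter=2500, burnin=500, thin=4, seed=3), d


class TestFitMCMC:
    def test_posterior_partition_recovers_truth(self, mcmc_fit):
        fit, _ = mcmc_fit
        assert fit.partition["R2p"] == pytest.approx(0.8, abs=0.12)

    def test_consistent_with_ml(self, mcmc_fit):
        fit, d = mcmc_fit
        ml = pmm.fit_pmm_ml(d)
        assert fit.partition["R2p"] == pytest.approx(ml.partition["R2p"],
                                                     abs=0.05)

    def test_summary_fields_and_chain(self, mcmc_fit):
        fit, _ = mcmc_fit
        assert set(fit.mcmc.columns) == {"Post.mean", "lower95", "upper95",
                                         "Eff.samp", "pMCMC"}
        assert fit.chain is not None and "sigma2_p" in fit.chain.columns
        assert (fit.mcmc["Eff.samp"] > 50).all()

    def test_null_coefficient_pmcmc_not_extreme(self):
        sim = recovery_sim(21, n_species=80, s2p=0.2, s2s=0.1, s2e=0.2)
        d = pmm.build_design(sim.table, sim.tree, ["mat"])  # true beta 0
        fit = pmm.fit_pmm_mcmc(d, n_iter=1500, burnin=300, thin=3, seed=4)
        assert fit.mcmc.loc["mat", "pMCMC"] > 0.01

    def test_seed_reproducible(self):
        sim = recovery_sim(22, n_species=40)
        d = pmm.build_design(sim.table, sim.tree, [])
        a = pmm.fit_pmm_mcmc(d, n_iter=600, burnin=100, thin=2, seed=9)
        b = pmm.fit_pmm_mcmc(d, n_iter=600, burnin=100, thin=2, seed=9)
        pd.testing.assert_frame_equal(a.chain, b.chain)


class TestSelection:
    def make_table(self, seed, signal=2.0, n=2000):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame({c: rng.uniform(0, 1, n)
                          for c in ["mat", "map", "clay", "ndvi"]})
        t["wood_density"] = signal * t["mat"] + rng.normal(0, 1, n)
        return t

    def test_bic_recovers_true_predictor(self):
        hits = sum(
            pmm.select_fixed_effects(self.make_table(s), ["mat", "map",
                                                          "clay", "ndvi"],
                                     criterion="bic").best == ("mat",)
            for s in range(20))
        assert hits >= 18

    def test_aic_always_keeps_true_predictor(self):
        for s in range(5):
            best = pmm.select_fixed_effects(self.make_table(s),
                                            ["mat", "map", "clay", "ndvi"]).best
            assert "mat" in best

    def test_null_response_prefers_empty_model_bic(self):
        hits = sum(
            pmm.select_fixed_effects(self.make_table(s, signal=0.0),
                                     ["mat", "map", "clay", "ndvi"],
                                     criterion="bic").best == ()
            for s in range(10))
        assert hits >= 9

    def test_ranking_table_complete(self):
        sel = pmm.select_fixed_effects(self.make_table(0), ["mat", "map"])
        assert len(sel.table) == 4  # 2^2 subsets
        assert sel.table["aic"].is_monotonic_increasing

    def test_tie_prefers_smaller_then_lexicographic(self):
        # duplicated predictor -> identical fits, AIC ties exactly
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"a": rng.normal(size=200)})
        t["b"] = t["a"]
        t["wood_density"] = rng.normal(size=200)
        sel = pmm.select_fixed_effects(t, ["a", "b"])
        assert len(sel.best) <= 1

    def test_too_many_candidates(self):
        t = self.make_table(0)
        with pytest.raises(ValueError, match="12"):
            pmm.select_fixed_effects(t, [f"c{i}" for i in range(13)])


class TestEnvR2:
    def test_exact_linear_r2_one(self):
        t = pd.DataFrame({"mat": np.linspace(0, 10, 50)})
        t["wood_density"] = 0.3 + 0.02 * t["mat"]
        res = pmm.env_only_r2(t, ["mat"])
        assert res.r2 == pytest.approx(1.0)

    def test_independent_response_low_r2(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame({c: rng.uniform(size=10_000)
                          for c in ["mat", "map", "clay", "ndvi"]})
        t["wood_density"] = rng.normal(size=10_000)
        assert pmm.env_only_r2(t, ["mat", "map", "clay", "ndvi"]).r2 < 0.01

    def test_duplicated_column_rank_error(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame({"mat": rng.normal(size=50)})
        t["mat2"] = t["mat"]
        t["wood_density"] = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            pmm.env_only_r2(t, ["mat", "mat2"])


class _Linear:
    def __init__(self, table, cols):
        self.cols = cols
        X = np.column_stack([np.ones(len(table)), table[cols].to_numpy()])
        self.beta = np.linalg.lstsq(X, table["wood_density"].to_numpy(),
                                    rcond=None)[0]

    def predict(self, table):
        X = np.column_stack([np.ones(len(table)), table[self.cols].to_numpy()])
        return X @ self.beta


class TestImportance:
    def make(self, seed, n=800):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n),
                          "x3": rng.normal(size=n)})
        t["wood_density"] = (2 * t["x1"] + 0.1 * t["x2"]
                             + rng.normal(0, 1, n))
        return t

    def test_identity_permutation_scores_zero(self):
        t = self.make(0)
        model = _Linear(t, ["x1", "x2", "x3"])
        score = pmm.score_single_permutation(model, t, "x1", np.arange(len(t)))
        assert score == 0.0

    def test_strong_predictor_ranked_first(self):
        wins = 0
        for seed in range(20):
            t = self.make(seed)
            model = _Linear(t, ["x1", "x2", "x3"])
            res = pmm.permutation_importance(model, t, ["x1", "x2", "x3"],
                                             n_repeats=10, seed=seed)
            top = res.scores.set_index("variable")["rank"]
            wins += top["x1"] == 1
        assert wins >= 19

    def test_null_variable_near_zero(self):
        t = self.make(5)
        model = _Linear(t, ["x1", "x2", "x3"])
        res = pmm.permutation_importance(model, t, ["x3"], n_repeats=20,
                                         seed=1)
        row = res.scores.iloc[0]
        assert abs(row["score"]) < 2 * row["se"] + 1e-6

    def test_ranks_are_permutation(self):
        t = self.make(2)
        model = _Linear(t, ["x1", "x2", "x3"])
        res = pmm.permutation_importance(model, t, ["x1", "x2", "x3"],
                                         n_repeats=5, seed=2)
        assert sorted(res.scores["rank"]) == [1, 2, 3]

    def test_invalid_repeats(self):
        t = self.make(3)
        with pytest.raises(ValueError):
            pmm.permutation_importance(_Linear(t, ["x1"]), t, ["x1"],
                                       n_repeats=0)


class TestPartialEffects:
    def test_negative_slope_recovered(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame({"mat": rng.uniform(0, 10, 500)})
        t["wood_density"] = 1.0 - 3.0 * t["mat"] + rng.normal(0, 0.5, 500)
        res = pmm.env_only_r2(t, ["mat"])
        eff = pmm.partial_effects(res, "mat", table=t)
        assert eff.sign == "-"
        assert eff.slope == pytest.approx(-3.0, abs=0.1)

    def test_zero_coefficient_interval_covers_zero(self):
        covered = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            t = pd.DataFrame({"mat": rng.uniform(0, 1, 200),
                              "map": rng.uniform(0, 1, 200)})
            t["wood_density"] = 2 * t["mat"] + rng.normal(0, 0.5, 200)
            res = pmm.env_only_r2(t, ["mat", "map"])
            eff = pmm.partial_effects(res, "map", table=t)
            covered += eff.lower95 <= 0 <= eff.upper95
        assert 32 <= covered <= 40  # ~95% nominal coverage

    def test_pmm_fit_variant_and_partial_residuals(self):
        sim = recovery_sim(30, n_species=40,
                           beta={**zero_beta(), "mat": 0.01})
        d = pmm.build_design(sim.table, sim.tree, ["mat"])
        fit = pmm.fit_pmm_ml(d)
        eff = pmm.partial_effects(fit, "mat")
        assert eff.slope == pytest.approx(
            fit.beta.loc["mat", "estimate"])
        assert len(eff.points) == d.n_rows

    def test_unknown_variable(self):
        sim = recovery_sim(31, n_species=20)
        d = pmm.build_design(sim.table, sim.tree, [])
        fit = pmm.fit_pmm_ml(d)
        with pytest.raises(KeyError):
            pmm.partial_effects(fit, "mat")
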