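"""Statistical core: GLS mean, Blomberg's K, PGLS/RRPP, two-block PLS."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from viperpcm.pcm import (
    PGLS,
    PhylogeneticSignal,
    TwoBlockPLS,
    blomberg_k,
    multi_tree_run,
    pairwise_pgls,
    phylo_gls_mean,
    phylo_pls,
    phylosig_test,
    rrpp_significance,
    spawn_seeds,
    two_block_pls,
)
from viperpcm.synth import simulate_bm_trait, simulate_yule_tree
from viperpcm.treeops import phylo_covariance


class TestGLSMean:
    def test_identity_cov_is_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        assert phylo_gls_mean(x, np.eye(12)) == pytest.approx(x.mean(), abs=1e-12)

    def test_star_tree_is_arithmetic_mean(self, star_cov):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        assert phylo_gls_mean(x, star_cov) == pytest.approx(x.mean(), abs=1e-12)

    def test_three_tip_brute_force(self, three_tip):
        C = phylo_covariance(three_tip).reorder(["A", "B", "C"])
        x = np.array([0.0, 0.0, 4.0])
        Cinv = np.linalg.inv(C.matrix)
        one = np.ones(3)
        expected = (one @ Cinv @ x) / (one @ Cinv @ one)
        assert phylo_gls_mean(x, C.matrix) == pytest.approx(expected, abs=1e-12)

    def test_singular_cov_reported(self):
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            phylo_gls_mean(np.ones(3), np.ones((3, 3)))


class TestBlombergK:
    def test_star_tree_k_is_one_exactly(self, star_cov):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal(10)
            assert blomberg_k(x, star_cov).K == pytest.approx(1.0, abs=1e-10)

    def test_internal_ratio_consistency(self, yule39, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=3)
        res = blomberg_k(x, yule39_cov)
        assert res.K == pytest.approx(
            (res.mse0 / res.mse) / res.expected_ratio, rel=1e-12
        )
        assert res.K > 0

    def test_zero_variance_error(self, star_cov):
        with pytest.raises(ValueError, match="zero variance"):
            blomberg_k(np.ones(10), star_cov)

    def test_matches_phytools(self, tmp_path):
        """Independent oracle: phytools::phylosig on the same tree and trait."""
        tree = simulate_yule_tree(20, seed=3, depth=10.0)
        C = phylo_covariance(tree)
        x = simulate_bm_trait(C, seed=4)
        (tmp_path / "t.nwk").write_text(tree.as_newick())
        x.to_csv(tmp_path / "x.csv", header=False)
        script = (
            'suppressMessages(library(phytools));'
            f'tr <- read.tree("{tmp_path / "t.nwk"}");'
            f'd <- read.csv("{tmp_path / "x.csv"}", header=FALSE, row.names=1);'
            'x <- setNames(d$V2, rownames(d));'
            'cat(sprintf("%.12f", phylosig(tr, x, method="K")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert blomberg_k(x, C).K == pytest.approx(float(out.stdout), abs=1e-8)


class TestPhylosigTest:
    def test_star_tree_forced_ties_give_p_one(self, star_cov):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        res = phylosig_test(x, star_cov, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_bounds_and_reproducibility(self, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=5)
        a = phylosig_test(x, yule39_cov, n_perm=199, seed=42)
        b = phylosig_test(x, yule39_cov, n_perm=199, seed=42)
        assert a.p_value == b.p_value
        assert 1 / 200 <= a.p_value <= 1.0

    def test_strong_bm_signal_detected(self, yule39_cov):
        hits = 0
        for i in range(20):
            x = simulate_bm_trait(yule39_cov, seed=100 + i)
            if phylosig_test(x, yule39_cov, n_perm=199, seed=i).p_value <= 0.05:
                hits += 1
        assert hits >= 17

    def test_shuffled_labels_lose_signal(self, yule39_cov):
        rng = np.random.default_rng(6)
        ks = []
        for i in range(30):
            x = simulate_bm_trait(yule39_cov, seed=200 + i).to_numpy()
            ks.append(blomberg_k(rng.permutation(x), yule39_cov.matrix).K)
        assert np.mean(ks) < 0.6


class TestPGLS:
    def test_identity_cov_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 2))
        y = X @ [1.5, -2.0] + rng.standard_normal(30)
        est = PGLS(cov=None, n_perm=0).fit(X, y)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], ols.params, atol=1e-10
        )
        assert est.r2_ == pytest.approx(ols.rsquared, abs=1e-10)
        assert est.f_ == pytest.approx(ols.fvalue, abs=1e-8)

    def test_noise_free_exact_fit(self, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=8).to_numpy()
        y = 2.0 + 3.0 * x
        est = PGLS(cov=yule39_cov, n_perm=0).fit(x[:, None], y)
        assert est.intercept_ == pytest.approx(2.0, abs=1e-8)
        assert est.coef_[0] == pytest.approx(3.0, abs=1e-10)
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_six_tip_brute_force_oracle(self):
        """Explicit-inverse GLS on a hand-built 6-tip chronogram."""
        from viperpcm.treeops import Chronogram

        tree = Chronogram.from_newick(
            "(((A:1,B:1):2,(C:2,D:2):1):3,(E:4,F:4):2);"
        )
        C = phylo_covariance(tree).reorder(list("ABCDEF"))
        rng = np.random.default_rng(9)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        Cinv = np.linalg.inv(C.matrix)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ y)
        est = PGLS(cov=C, n_perm=0).fit(pd.Series(x, index=list("ABCDEF")),
                                        pd.Series(y, index=list("ABCDEF")))
        np.testing.assert_allclose(np.r_[est.intercept_, est.coef_], beta, atol=1e-10)
        # R2/F recomputed independently in the whitened space
        lam, U = np.linalg.eigh(C.matrix)
        P = U @ np.diag(lam**-0.5) @ U.T
        ys, Xs = P @ y, P @ X
        fit_full = Xs @ beta
        x0 = P @ np.ones(6)
        a0 = (x0 @ ys) / (x0 @ x0)
        sst = np.sum((ys - a0 * x0) ** 2)
        sse = np.sum((ys - fit_full) ** 2)
        assert est.r2_ == pytest.approx((sst - sse) / sst, abs=1e-10)
        assert est.f_ == pytest.approx(((sst - sse) / 1) / (sse / 4), abs=1e-8)

    def test_collinear_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            PGLS(n_perm=0).fit(X, np.arange(10.0))

    def test_too_few_tips(self):
        with pytest.raises(ValueError, match="n > p"):
            PGLS(n_perm=0).fit(np.zeros((3, 2)), np.zeros(3))


class TestRRPP:
    def test_strong_association_min_p(self, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=10).to_numpy()
        y = 2 * x + 0.05 * np.random.default_rng(0).standard_normal(39)
        p, z = rrpp_significance(y, x[:, None], yule39_cov, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)
        assert z > 2

    def test_agrees_with_parametric_f_test_under_identity(self):
        rng = np.random.default_rng(11)
        diffs = []
        for i in range(10):
            x = rng.standard_normal(40)
            y = 0.4 * x + rng.standard_normal(40)
            est = PGLS(cov=None, n_perm=1999, random_state=i).fit(x[:, None], y)
            diffs.append(
                est.p_value_ - stats.f.sf(est.f_, est.df_model_, est.df_resid_)
            )
        assert np.max(np.abs(diffs)) < 0.02

    def test_low_perm_count_warns(self, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=12).to_numpy()
        y = simulate_bm_trait(yule39_cov, seed=13).to_numpy()
        with pytest.warns(UserWarning, match="resolution"):
            rrpp_significance(y, x[:, None], yule39_cov, n_perm=49, seed=0)

    def test_seeded_reproducibility(self, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=14).to_numpy()
        y = simulate_bm_trait(yule39_cov, seed=15).to_numpy()
        a = rrpp_significance(y, x[:, None], yule39_cov, n_perm=199, seed=3)
        b = rrpp_significance(y, x[:, None], yule39_cov, n_perm=199, seed=3)
        assert a == b


class TestTwoBlockPLS:
    def test_one_by_one_blocks_equal_abs_pearson(self):
        rng = np.random.default_rng(16)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        res = two_block_pls(a, b, n_perm=0)
        assert res.r == pytest.approx(abs(np.corrcoef(a, b)[0, 1]), abs=1e-12)

    def test_duplicate_block_r_is_one(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((20, 3))
        assert two_block_pls(X, X.copy(), n_perm=0).r == pytest.approx(1.0, abs=1e-10)

    def test_planted_correlation_recovered_n200(self):
        rng = np.random.default_rng(18)
        n = 200
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        u = (u - z * (z @ u) / (z @ z))
        u /= u.std()
        e = 0.7 * (z / z.std()) + np.sqrt(1 - 0.49) * u
        # keep within-block noise small so the score correlation stays ~0.7
        X = np.outer(z, [0.8, 0.6]) + 0.1 * rng.standard_normal((n, 2))
        Y = np.outer(e, [0.5, -0.5, 0.7]) + 0.1 * rng.standard_normal((n, 3))
        assert two_block_pls(X, Y, n_perm=0).r == pytest.approx(0.7, abs=0.05)

    def test_rotation_invariance_of_r(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((25, 4))
        Y = X @ rng.standard_normal((4, 5)) + 0.5 * rng.standard_normal((25, 5))
        r0 = two_block_pls(X, Y, n_perm=0).r
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        r1 = two_block_pls(X @ Q, Y, n_perm=0).r
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_sign_convention_and_unit_norm(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 4))
        res = two_block_pls(X, Y, n_perm=0)
        assert np.linalg.norm(res.left_loadings) == pytest.approx(1.0)
        assert np.linalg.norm(res.right_loadings) == pytest.approx(1.0)
        u = res.left_loadings
        assert u[np.argmax(np.abs(u))] > 0

    def test_constant_column_warns(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((15, 2))
        Y = np.column_stack([np.ones(15), rng.standard_normal(15)])
        with pytest.warns(UserWarning, match="constant"):
            two_block_pls(X, Y, n_perm=0)

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((20, 2))
        Y = rng.standard_normal((20, 3))
        assert (
            two_block_pls(X, Y, n_perm=99, seed=5).p_value
            == two_block_pls(X, Y, n_perm=99, seed=5).p_value
        )


class TestPhyloPLS:
    def test_star_tree_equals_naive(self, star_cov):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 4))
        r_naive = two_block_pls(X, Y, n_perm=0).r
        r_phylo = phylo_pls(X, Y, star_cov, n_perm=0).r
        assert r_phylo == pytest.approx(r_naive, abs=1e-10)

    def test_estimator_modes(self, yule39_cov):
        X = np.random.default_rng(24).standard_normal((39, 2))
        Y = np.random.default_rng(25).standard_normal((39, 5))
        assert TwoBlockPLS(cov=None, n_perm=0).fit(X, Y).mode_ == "naive"
        assert TwoBlockPLS(cov=yule39_cov, n_perm=0).fit(X, Y).mode_ == "phylogenetic"


class TestMultiTree:
    def test_identical_trees_zero_dispersion(self, yule39, yule39_cov):
        x = simulate_bm_trait(yule39_cov, seed=26)

        def analysis(tree, seed):
            res = blomberg_k(x, phylo_covariance(tree))
            return {"K": res.K, "p_value": 0.01}

        summary = multi_tree_run(analysis, [yule39] * 10, seed=0)
        assert summary.dispersion["K"] == pytest.approx(0.0, abs=1e-12)
        assert summary.mean["K"] == pytest.approx(blomberg_k(x, yule39_cov).K)
        assert summary.n_significant == 10

    def test_n_significant_matches_recount(self):
        trees = [simulate_yule_tree(8, seed=i, depth=5.0) for i in range(30)]

        def analysis(tree, seed):
            rng = np.random.default_rng(seed)
            return {"p_value": float(rng.random())}

        summary = multi_tree_run(analysis, trees, seed=99, alpha=0.5)
        recount = int((summary.per_tree["p_value"] < 0.5).sum())
        assert summary.n_significant == recount

    def test_failures_excluded_with_warning(self, yule39):
        def analysis(tree, seed):
            if analysis.calls == 1:
                analysis.calls += 1
                raise RuntimeError("boom")
            analysis.calls += 1
            return {"p_value": 0.2, "stat": 1.0}

        analysis.calls = 0
        with pytest.warns(UserWarning, match="failed on tree"):
            summary = multi_tree_run(analysis, [yule39] * 5, seed=0)
        assert summary.n_trees == 4 and summary.n_failed == 1

    def test_pooled_mean_is_weighted_batch_mean(self):
        trees = [simulate_yule_tree(6, seed=i, depth=5.0) for i in range(12)]

        def analysis(tree, seed):
            return {"stat": float(tree.root_depth + len(tree.tips))}

        full = multi_tree_run(analysis, trees, seed=0)
        a = multi_tree_run(analysis, trees[:4], seed=0)
        b = multi_tree_run(analysis, trees[4:], seed=0)
        pooled = (4 * a.mean["stat"] + 8 * b.mean["stat"]) / 12
        assert full.mean["stat"] == pytest.approx(pooled, rel=1e-12)


class TestPairwisePGLS:
    def test_full_grid_with_holm(self, yule39_cov):
        labels = yule39_cov.labels
        rng = np.random.default_rng(27)
        traits = pd.DataFrame(
            rng.standard_normal((39, 2)), index=labels, columns=["wpi", "dm"]
        )
        desc = pd.DataFrame(
            rng.standard_normal((39, 3)), index=labels, columns=["A", "B", "C"]
        )
        out = pairwise_pgls(traits, desc, yule39_cov, n_perm=99, seed=0)
        assert len(out) == 6
        assert set(out["trait"]) == {"wpi", "dm"}
        adj = pairwise_pgls(traits, desc, yule39_cov, n_perm=99, seed=0, holm=True)
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-12).all()
        # same seed protocol -> identical raw p-values either way
        np.testing.assert_allclose(out["p_value"], adj["p_value"])

    def test_misaligned_rows_rejected(self, yule39_cov):
        labels = yule39_cov.labels
        traits = pd.DataFrame({"t": np.arange(39.0)}, index=labels)
        desc = pd.DataFrame({"d": np.arange(39.0)}, index=list(reversed(labels)))
        with pytest.raises(ValueError, match="row labels"):
            pairwise_pgls(traits, desc, yule39_cov)


def test_spawn_seeds_counter_keyed():
    a = spawn_seeds(5, 4)
    b = spawn_seeds(5, 8)
    for i in range(4):
        assert (
            np.random.default_rng(a[i]).integers(1 << 30)
            == np.random.default_rng(b[i]).integers(1 << 30)
        )
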