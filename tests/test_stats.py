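import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treesignal as ts
from treesignal.stats import GlsCache, blomberg_k_batch, morans_i_batch

from conftest import oracle_morans_i, random_tree


def _random_weight_matrix(rng, n):
    W = rng.uniform(0.0, 1.0, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestMoransI:
    def test_two_tips_forced_minus_one(self):
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        assert np.isclose(ts.morans_i([1.0, -1.0], W, _n_min=2), -1.0)

    def test_matches_double_loop_oracle_500_cases(self):
        rng = np.random.default_rng(100)
        for _ in range(500):
            n = int(rng.integers(3, 11))
            y = rng.standard_normal(n)
            W = _random_weight_matrix(rng, n)
            assert abs(ts.morans_i(y, W) - oracle_morans_i(y, W)) < 1e-12

    def test_constant_trait_rejected(self):
        W = _random_weight_matrix(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="zero variance"):
            ts.morans_i(np.ones(5), W)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ts.morans_i([1.0, 2.0], np.zeros((2, 2)))

    @given(
        a=st.floats(min_value=-10, max_value=10).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-10, max_value=10),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        y = rng.standard_normal(n)
        W = _random_weight_matrix(rng, n)
        assert np.isclose(ts.morans_i(y, W), ts.morans_i(a * y + b, W), atol=1e-9)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(101)
        W = _random_weight_matrix(rng, 8)
        Y = rng.standard_normal((20, 8))
        batch = morans_i_batch(Y, W)
        single = [ts.morans_i(y, W) for y in Y]
        assert np.allclose(batch, single)


class TestCmean:
    def test_identity_with_abouheif_moran(self):
        rng = np.random.default_rng(102)
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(4, 15)))
            y = rng.standard_normal(tree.n_tips)
            W = ts.abouheif_proximity(tree)
            assert np.isclose(ts.abouheif_cmean(tree, y), ts.morans_i(y, W))

    def test_three_tip_hand_value(self, three_tip):
        y = np.array([1.0, 1.0, -2.0])
        W = np.array([[0, 0.5, 0.25], [0.5, 0, 0.25], [0.25, 0.25, 0]])
        assert np.isclose(ts.abouheif_cmean(three_tip, y), oracle_morans_i(y, W))


class TestLocalMoran:
    def test_m2_hand_value(self):
        W = _random_weight_matrix(np.random.default_rng(1), 3)
        y = np.array([1.0, 2.0, 3.0])
        z = y - 2.0
        m2 = 2.0 / 3.0
        expected = (z / m2) * (W @ z)
        assert np.allclose(ts.local_morans_i(y, W), expected)

    def test_sum_identity_against_global(self):
        rng = np.random.default_rng(103)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            y = rng.standard_normal(n)
            W = _random_weight_matrix(rng, n)
            total = ts.local_morans_i(y, W).sum()
            assert np.isclose(total, ts.morans_i(y, W) * W.sum(), atol=1e-10)

    def test_zero_when_neighbors_at_mean(self):
        # tip 0 only connects to tip 1, which sits exactly at the mean
        y = np.array([5.0, 2.0, 1.0, 0.0])  # mean 2
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        assert np.isclose(ts.local_morans_i(y, W)[0], 0.0)


class TestBlombergK:
    def test_star_tree_k_is_one(self, star4):
        V = ts.bm_covariance(star4)
        rng = np.random.default_rng(104)
        for _ in range(10):
            y = rng.standard_normal(4)
            assert np.isclose(ts.blomberg_k(V, y), 1.0)
            assert np.isclose(ts.blomberg_kstar(V, y), 1.0)

    def test_k_equals_kstar_under_identity_covariance(self):
        V = ts.CovarianceMatrix(np.eye(6), tuple("abcdef"))
        rng = np.random.default_rng(105)
        y = rng.standard_normal(6)
        assert np.isclose(ts.blomberg_k(V, y), ts.blomberg_kstar(V, y))

    def test_scale_invariance(self):
        rng = np.random.default_rng(106)
        tree = random_tree(rng, 12)
        V = ts.bm_covariance(tree)
        y = rng.standard_normal(12)
        k = ts.blomberg_k(V, y)
        # scaling every branch length by c scales V by c
        scaled_v = ts.CovarianceMatrix(V.values * 3.7, V.labels)
        assert np.isclose(ts.blomberg_k(scaled_v, y * 0.21), k)
        assert np.isclose(
            ts.blomberg_kstar(scaled_v, y * 0.21), ts.blomberg_kstar(V, y)
        )

    def test_mean_k_near_one_under_bm(self):
        tree = ts.simulate_yule_tree(100, seed=42)
        V = ts.bm_covariance(tree)
        cache = GlsCache.from_covariance(V)
        Y = ts.simulate_bm(tree, seed=43, n_traits=500).T
        ks = blomberg_k_batch(Y, cache)
        assert abs(ks.mean() - 1.0) < 0.1

    def test_singular_covariance_message(self):
        V = ts.CovarianceMatrix(np.ones((4, 4)), tuple("abcd"))
        with pytest.raises(ValueError, match="singular"):
            ts.blomberg_k(V, np.array([1.0, 2.0, 3.0, 4.0]))


class TestPagelLambda:
    def test_recovery_under_bm_and_noise(self):
        tree = ts.simulate_yule_tree(100, seed=7)
        V = ts.bm_covariance(tree)
        rng = np.random.default_rng(8)
        lam_bm = [
            ts.pagel_lambda_ml(V, ts.simulate_bm(tree, seed=rng))[0] for _ in range(30)
        ]
        lam_noise = [
            ts.pagel_lambda_ml(V, rng.standard_normal(100))[0] for _ in range(30)
        ]
        assert np.median(lam_bm) >= 0.9
        assert np.median(lam_noise) <= 0.1

    def test_optimum_beats_bounds(self):
        rng = np.random.default_rng(9)
        tree = random_tree(rng, 30)
        V = ts.bm_covariance(tree)
        y = 0.6 * ts.simulate_bm(tree, seed=rng) + 0.4 * rng.standard_normal(30)
        lam, ll_hat, ll0 = ts.pagel_lambda_ml(V, y)
        from treesignal.stats import _profile_loglik

        assert ll_hat >= _profile_loglik(0.0, V, y) - 1e-9
        assert ll_hat >= _profile_loglik(1.0, V, y) - 1e-9

    def test_flat_profile_star_tree_warns_zero(self):
        star = ts.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        V = ts.bm_covariance(star)
        y = np.array([0.1, -0.4, 1.2, 0.5, -0.9])
        with pytest.warns(UserWarning, match="flat likelihood"):
            lam, _, _ = ts.pagel_lambda_ml(V, y)
        assert lam == 0.0


class TestAgainstIndependentImplementation:
    def test_k_and_lambda_match_r_phytools(self, tmp_path):
        """K and lambda agree with an independent ML implementation
        (phytools::phylosig) on the same tree and trait."""
        tree = ts.simulate_yule_tree(15, seed=77)
        rng = np.random.default_rng(78)
        y = ts.simulate_bm(tree, seed=rng) + 0.4 * rng.standard_normal(15)
        ts.write_newick(tree, tmp_path / "t.nwk")
        pd.DataFrame({"y": y}, index=tree.tip_labels).rename_axis("tip").to_csv(
            tmp_path / "y.csv"
        )
        script = textwrap.dedent("""
            suppressMessages({library(ape); library(phytools)})
            tr <- read.tree("t.nwk")
            d <- read.csv("y.csv", row.names = 1)
            y <- setNames(d$y, rownames(d))
            l <- phylosig(tr, y, method = "lambda")
            cat(phylosig(tr, y, method = "K"), l$lambda, l$logL, sep = "\\n")
        """)
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        r_k, r_lam, r_ll = map(float, out.stdout.strip().split("\n")[-3:])
        V = ts.bm_covariance(tree)
        lam, ll_hat, _ = ts.pagel_lambda_ml(V, y)
        assert np.isclose(ts.blomberg_k(V, y), r_k, atol=1e-5)
        assert np.isclose(lam, r_lam, atol=1e-3)
        assert np.isclose(ll_hat, r_ll, atol=1e-4)
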