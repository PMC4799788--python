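import itertools

import numpy as np
import pandas as pd
import pytest

import treesignal as ts
from treesignal.inference import _perm_pvalue, make_method_context, stat_and_test

from conftest import make_traittree, random_tree


class TestPvalueCounting:
    def test_observed_beats_all_permutations(self):
        null = np.linspace(-0.5, 0.4, 999)
        assert _perm_pvalue(0.9, null, "greater") == pytest.approx(1 / 1000)

    def test_two_sided_doubles_and_caps(self):
        null = np.linspace(-1, 1, 99)
        assert _perm_pvalue(0.0, null, "two-sided") == 1.0
        assert _perm_pvalue(2.0, null, "two-sided") == pytest.approx(2 / 100)

    def test_p_never_zero(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, 10)
        y = ts.simulate_bm(tree, seed=1) * 100  # extreme signal
        tt = make_traittree(tree, y)
        res = ts.permutation_test("Cmean", tt, "y", nrep=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_nrep_floor(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 8)
        tt = make_traittree(tree, rng.standard_normal(8))
        with pytest.raises(ValueError, match="nrep"):
            ts.permutation_test("I", tt, "y", nrep=10)


class TestPermutationNull:
    def test_mean_permuted_moran_full_enumeration_n6(self):
        """Over all 720 permutations of 6 values the mean of Moran's I is
        exactly -1/(n-1), whatever the weights."""
        rng = np.random.default_rng(2)
        tree = random_tree(rng, 6)
        W = ts.inverse_distance_weights(ts.patristic_distances(tree))
        y = rng.standard_normal(6)
        perms = np.array(list(itertools.permutations(y)))
        stats = ts.stats.morans_i_batch(perms, W)
        assert np.isclose(stats.mean(), -1.0 / 5.0, atol=1e-12)

    def test_sampled_permutation_p_converges_to_enumeration(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 6)
        W = ts.inverse_distance_weights(ts.patristic_distances(tree))
        y = rng.standard_normal(6)
        obs = ts.morans_i(y, W)
        perms = np.array(list(itertools.permutations(y)))
        exact = np.mean(ts.stats.morans_i_batch(perms, W) >= obs)
        tt = make_traittree(tree, y)
        res = ts.permutation_test("I", tt, "y", nrep=9999, seed=4)
        assert abs(res.p_value - exact) < 0.02

    def test_type_i_error_small_batch(self):
        """Null rejection rate of the Cmean randomization test is close to
        nominal; the full-scale calibration lives in the acceptance suite."""
        rng = np.random.default_rng(5)
        tree = random_tree(rng, 15)
        ctx = make_method_context(tree, ("Cmean",))
        rejections = 0
        nsim = 200
        for s in range(nsim):
            y = rng.standard_normal(15)
            _, p = stat_and_test(ctx, "Cmean", y, nrep=199, seed=s)
            rejections += p < 0.05
        assert 0.01 <= rejections / nsim <= 0.10


class TestLambdaLrt:
    def test_boundary_lambda_zero(self, star4):
        with pytest.warns(UserWarning, match="flat"):
            res = ts.lambda_lrt(ts.bm_covariance(star4), np.array([0.3, -1.0, 0.6, 1.4]))
        assert res.stat == 0.0
        assert res.p_value == 1.0

    def test_chi_square_reference(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_bm_trait_rejects(self):
        tree = ts.simulate_yule_tree(50, seed=6)
        y = ts.simulate_bm(tree, seed=7)
        res = ts.lambda_lrt(ts.bm_covariance(tree), y)
        assert res.stat > 0.8
        assert res.p_value < 0.05


class TestPhyloSignal:
    def test_table_shape_and_methods(self, yule17):
        rng = np.random.default_rng(8)
        traits = pd.DataFrame(
            {
                "BM": ts.simulate_bm(yule17, seed=9),
                "random": rng.standard_normal(17),
            },
            index=yule17.tip_labels,
        )
        tt = ts.bind_tree_traits(yule17, traits)
        tab = ts.phylo_signal(tt, nrep=199, seed=10)
        assert list(tab.stat.index) == ["BM", "random"]
        assert list(tab.stat.columns) == list(ts.METHODS)
        assert tab.pvalue.notna().all().all()

    def test_same_seed_identical_and_traits_independent(self, yule17):
        y = ts.simulate_bm(yule17, seed=11)
        traits = pd.DataFrame({"a": y, "b": y}, index=yule17.tip_labels)
        tt = ts.bind_tree_traits(yule17, traits)
        t1 = ts.phylo_signal(tt, nrep=199, seed=12)
        t2 = ts.phylo_signal(tt, nrep=199, seed=12)
        pd.testing.assert_frame_equal(t1.stat, t2.stat)
        pd.testing.assert_frame_equal(t1.pvalue, t2.pvalue)

    def test_method_subset_keeps_pvalues(self, yule17):
        """Dropping a method never changes the p-values of the others."""
        y = ts.simulate_bm(yule17, seed=13)
        tt = ts.bind_tree_traits(
            yule17, pd.DataFrame({"y": y}, index=yule17.tip_labels)
        )
        full = ts.phylo_signal(tt, nrep=199, seed=14)
        partial = ts.phylo_signal(tt, methods=("I", "K"), nrep=199, seed=14)
        assert partial.pvalue.loc["y", "I"] == full.pvalue.loc["y", "I"]
        assert partial.pvalue.loc["y", "K"] == full.pvalue.loc["y", "K"]

    def test_constant_trait_fails_per_cell(self, yule17):
        traits = pd.DataFrame(
            {"flat": np.ones(17), "ok": ts.simulate_bm(yule17, seed=15)},
            index=yule17.tip_labels,
        )
        tt = ts.TraitTree(yule17, traits)
        tab = ts.phylo_signal(tt, nrep=99, seed=16)
        assert tab.stat.loc["flat"].isna().all()
        assert tab.stat.loc["ok"].notna().all()
        assert any(t == "flat" for t, _ in tab.errors)


class TestLipa:
    def test_cherry_hotspot(self):
        """Two cherry tips sharing an extreme value score high positive
        local Moran's I, and shuffling destroys it on average."""
        tree = ts.read_newick("((A:0.2,B:0.2):2,((C:1,D:1):1,(E:1,F:1):1):0.2);")
        y = np.array([5.0, 5.2, 0.1, -0.3, 0.2, -0.1])
        tt = make_traittree(tree, y)
        res = ts.lipa(tt, "y", nrep=999, seed=17)
        labels = tree.tip_labels
        ia, ib = labels.index("A"), labels.index("B")
        assert res.local_i[ia] > 0 and res.local_i[ib] > 0
        assert res.p_value[ia] < 0.05

    def test_sum_matches_global_moran(self, yule17):
        y = ts.simulate_bm(yule17, seed=18)
        tt = make_traittree(yule17, y)
        res = ts.lipa(tt, "y", nrep=99, seed=19)
        W = ts.inverse_distance_weights(ts.patristic_distances(yule17))
        assert np.isclose(res.local_i.sum(), ts.morans_i(y, W) * W.s0, atol=1e-10)

    def test_nnodes_scheme_and_zero_distance_advice(self):
        with pytest.warns(UserWarning):
            tree = ts.read_newick("((A:0,B:0):1,(C:1,D:1):1);")
        tt = make_traittree(tree, np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="nNodes"):
            ts.lipa(tt, "y", prox="patristic", nrep=99, seed=20)
        res = ts.lipa(tt, "y", prox="nNodes", nrep=99, seed=20)
        assert len(res.local_i) == 4

    def test_bh_adjustment_monotone(self, yule17):
        y = ts.simulate_bm(yule17, seed=21)
        tt = make_traittree(yule17, y)
        res = ts.lipa(tt, "y", nrep=199, seed=22, bh_adjust=True)
        assert np.all(res.p_adjusted >= res.p_value - 1e-15)
        assert np.all(res.p_adjusted <= 1.0)
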