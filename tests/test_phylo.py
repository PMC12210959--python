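"""Distances and trees: allele-sharing distance arithmetic, NJ exactness
(with scikit-bio as the independent oracle), windowed bootstrap support,
outgroup rooting, and the distance-trait regression."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from deepeye import phylo, simulate
from deepeye.traits import shared_branch_covariance


def tree_distances(tree_obj):
    tips = sorted(t.name for t in tree_obj.tips())
    nodes = {t.name: t for t in tree_obj.tips()}
    n = len(tips)
    D = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = nodes[a].distance(nodes[tips[j]])
    return pd.DataFrame(D, index=tips, columns=tips)


class TestPairwiseDistance:
    def test_identical_samples_distance_zero(self):
        g = np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=float)
        D = phylo.pairwise_distance(g, ["a", "b"])
        assert D.loc["a", "b"] == 0.0

    def test_forced_arithmetic(self):
        g = np.array([[0, 2], [2, 2]], dtype=float)
        D = phylo.pairwise_distance(g, ["a", "b"])
        assert D.loc["a", "b"] == pytest.approx(0.5)

    def test_matches_sitewise_loop_oracle(self, rng):
        g = rng.integers(0, 3, size=(5, 100)).astype(float)
        g[rng.random((5, 100)) < 0.1] = np.nan
        D = phylo.pairwise_distance(g, list("abcde"))
        for i in range(5):
            for j in range(i + 1, 5):
                num = cnt = 0.0
                for s in range(100):
                    if not (np.isnan(g[i, s]) or np.isnan(g[j, s])):
                        num += abs(g[i, s] - g[j, s]) / 2
                        cnt += 1
                assert D.iloc[i, j] == pytest.approx(num / cnt, abs=1e-12)

    def test_order_invariance(self, rng):
        g = rng.integers(0, 3, size=(4, 60)).astype(float)
        D1 = phylo.pairwise_distance(g, list("abcd"))
        perm = rng.permutation(60)
        D2 = phylo.pairwise_distance(g[:, perm], list("abcd"))
        assert np.allclose(D1, D2)
        rperm = [2, 0, 3, 1]
        D3 = phylo.pairwise_distance(g[rperm], [list("abcd")[i] for i in rperm])
        assert np.allclose(D1.loc[list("abcd"), list("abcd")], D3.loc[list("abcd"), list("abcd")])

    def test_no_shared_sites_errors(self):
        g = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="no non-missing"):
            phylo.pairwise_distance(g, ["a", "b"])


class TestNeighborJoining:
    ADDITIVE4 = pd.DataFrame(
        np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
        index=list("ABCD"), columns=list("ABCD"),
    )

    def test_four_taxon_split_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): internal branch 1, split AB|CD
        t = phylo.neighbor_joining(self.ADDITIVE4)
        assert phylo.bipartitions(t) == {frozenset({"C", "D"})}
        assert np.allclose(tree_distances(t), self.ADDITIVE4, atol=1e-12)
        a = t.find("A")
        b = t.find("B")
        assert a.length == pytest.approx(1.0)
        assert b.length == pytest.approx(2.0)
        assert a.parent is b.parent
        internal = a.parent
        assert internal.length == pytest.approx(1.0)

    def test_against_skbio_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 9))
            tr = simulate.random_tree(n, seed=int(rng.integers(1000)))
            D = tree_distances(tr)
            ours = phylo.neighbor_joining(D)
            ref = skbio_nj(DistanceMatrix(D.to_numpy(), list(D.index)))
            assert phylo.bipartitions(ours) == phylo.bipartitions(ref)
            assert np.allclose(tree_distances(ours), tree_distances(ref), atol=1e-9)

    def test_three_taxa_exact(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 8], [9, 8, 0]], index=list("XYZ"), columns=list("XYZ"), dtype=float
        )
        t = phylo.neighbor_joining(D)
        assert t.find("X").length == pytest.approx((5 + 9 - 8) / 2)
        assert t.find("Y").length == pytest.approx((5 + 8 - 9) / 2)
        assert t.find("Z").length == pytest.approx((9 + 8 - 5) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_trees(self, seed):
        n = 5 + seed % 16
        tr = simulate.random_tree(n, seed=seed)
        D = tree_distances(tr)
        out = phylo.neighbor_joining(D)
        assert np.allclose(tree_distances(out), D, atol=1e-9)

    def test_too_few_taxa(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"), dtype=float)
        with pytest.raises(ValueError, match="at least 3"):
            phylo.neighbor_joining(D)


class TestWindowBootstrap:
    def test_identical_windows_full_support(self, rng):
        tr = simulate.random_tree(6, seed=2)
        C, tips = shared_branch_covariance(tr)
        D = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        # dosage blocks engineered so every window yields distances ~ D
        # simpler: duplicate one window's genotypes across 4 windows
        g = rng.integers(0, 3, size=(6, 40)).astype(float)
        g = np.tile(g, (1, 4))
        pos = np.arange(1, 161) * 1000  # 4 windows of 100 kb holding 40 sites each
        chrom = np.repeat("chr1", 160)
        tree, support = phylo.window_bootstrap_support(
            g, list("abcdef"), chrom, pos, window_bp=40_000, replicates=30, seed=1
        )
        assert (support["support"] == 1.0).all()

    def test_supports_bounded(self, small_panel):
        panel, _ = small_panel
        sub = panel.dosages().astype(float)[:10]
        tree, support = phylo.window_bootstrap_support(
            sub, panel.samples[:10], panel.chrom, panel.pos,
            window_bp=200_000, replicates=20, seed=3,
        )
        assert ((support["support"] >= 0) & (support["support"] <= 1)).all()

    def test_conflicting_window_classes(self):
        # two window classes supporting AB|CD vs AC|BD mixed 50/50:
        # support of the contested edge tracks the resample majority
        def block(split):
            g = np.zeros((4, 30))
            if split == "AB":
                g[0] = g[1] = 2.0
            else:
                g[0] = g[2] = 2.0
            return g

        g = np.concatenate([block("AB"), block("AB"), block("AC"), block("AC")], axis=1)
        pos = np.concatenate([np.arange(30) * 100 + w * 100_000 + 1 for w in range(4)])
        chrom = np.repeat("chr1", 120)
        tree, support = phylo.window_bootstrap_support(
            g, list("ABCD"), chrom, pos, window_bp=100_000, replicates=400, seed=9
        )
        # exhaustive enumeration over 4^4 equally likely resamples, each
        # resolved by NJ on the window-averaged distance matrix (NJ exactness
        # is established independently above)
        from itertools import product

        per_window = [
            phylo.pairwise_distance(g[:, w * 30 : (w + 1) * 30], list("ABCD")).to_numpy()
            for w in range(4)
        ]
        wins = 0
        for draw in product(range(4), repeat=4):
            avg = np.mean([per_window[d] for d in draw], axis=0)
            D = pd.DataFrame(avg, index=list("ABCD"), columns=list("ABCD"))
            if frozenset({"C", "D"}) in phylo.bipartitions(phylo.neighbor_joining(D)):
                wins += 1
        expected = wins / 4**4
        got = support.set_index("bipartition")["support"].get("C;D", 0.0)
        assert abs(got - expected) < 0.08  # binomial error at B = 400


class TestRooting:
    def test_root_unroot_round_trip(self):
        tr = simulate.random_tree(7, seed=5)
        D = tree_distances(tr)
        unrooted = phylo.neighbor_joining(D)
        rooted = phylo.root_by_outgroup(unrooted, "t3")
        assert len(rooted.children) == 2
        rooted.unroot()
        assert phylo.bipartitions(rooted) == phylo.bipartitions(unrooted)

    def test_outgroup_pendant_midpoint(self):
        t = phylo.neighbor_joining(TestNeighborJoining.ADDITIVE4)
        rooted = phylo.root_by_outgroup(t, "D")
        d = rooted.find("D")
        assert d.parent is rooted or d.parent.parent is rooted
        sides = {c.name: c.length for c in rooted.children}
        assert sides.get("D") == pytest.approx(2.0)  # pendant edge 4.0 halved

    def test_missing_leaf_errors(self):
        t = phylo.neighbor_joining(TestNeighborJoining.ADDITIVE4)
        with pytest.raises(KeyError):
            phylo.root_by_outgroup(t, "nope")


class TestDistanceTraitRegression:
    def test_proportional_differences_r2_one(self):
        vals = pd.Series({"a": 0.0, "b": 1.0, "c": 3.0})
        D = pd.DataFrame(
            np.abs(vals.to_numpy()[:, None] - vals.to_numpy()[None, :]) * 2.0,
            index=vals.index, columns=vals.index,
        )
        out = phylo.distance_trait_regression(D, vals)
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.5)

    def test_constant_trait(self):
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        with pytest.warns(UserWarning, match="constant"):
            out = phylo.distance_trait_regression(D, pd.Series({"a": 1.0, "b": 1.0, "c": 1.0}))
        assert out["r2"] == 0.0
        assert out["slope"] == 0.0

    def test_known_linear_dependence(self, rng):
        # |dtrait| = 0.8 d + noise: R^2 near closed-form expectation
        n = 40
        ids = [f"s{i}" for i in range(n)]
        base = rng.uniform(0, 1, n)
        D = pd.DataFrame(np.abs(base[:, None] - base[None, :]), index=ids, columns=ids)
        trait = pd.Series(0.8 * base + 0.02 * rng.standard_normal(n), index=ids)
        out = phylo.distance_trait_regression(D, trait)
        assert out["r2"] > 0.85
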