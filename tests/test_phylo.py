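import math

import numpy as np
import pytest

from dynevo import phylo, synthetic
from dynevo.evolution import MSA
from dynevo.phylo import AnnotatedTree


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths via dendropy."""
    spec = [{"size": n_taxa}]
    t, _ = synthetic.synth_tree(n_tips=max(4, n_taxa), clade_spec=[{"size": max(4, n_taxa)}],
                                seed=int(rng.integers(2**31)))
    return t


class TestDistanceMatrix:
    def test_identical_zero(self):
        m = MSA(ids=list("abc"), seqs=["AAAA"] * 3)
        d = phylo.distance_matrix(m)
        assert np.allclose(d.to_numpy(), 0.0)

    def test_identity_fraction(self):
        m = MSA(ids=list("abc"), seqs=["A" * 10, "A" * 8 + "RR", "A" * 10])
        d = phylo.distance_matrix(m, "identity")
        assert d.loc["a", "b"] == pytest.approx(0.2)

    def test_kimura_closed_form(self):
        m = MSA(ids=list("abc"), seqs=["A" * 10, "A" * 8 + "RR", "A" * 10])
        d = phylo.distance_matrix(m, "kimura")
        assert d.loc["a", "b"] == pytest.approx(-math.log(1 - 0.2 - 0.04 / 5), abs=1e-12)


class TestNjTree:
    def test_four_taxon_additive_recovery(self):
        """NJ on the additive matrix of ((A,B),(C,D)) recovers the split
        and the exact path distances."""
        nwk = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"
        ref = AnnotatedTree.from_newick(nwk)
        d = ref.tip_distance_matrix()
        t = phylo.nj_tree(d)
        d2 = t.tip_distance_matrix()
        assert np.allclose(d.to_numpy(), d2.loc[d.index, d.columns].to_numpy(),
                           atol=1e-9)

    def test_three_taxa_exact(self):
        import pandas as pd

        d = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        t = phylo.nj_tree(d)
        d2 = t.tip_distance_matrix()
        assert np.allclose(d.to_numpy(), d2.loc[d.index, d.columns].to_numpy(),
                           atol=1e-9)

    @pytest.mark.parametrize("rep", range(10))
    def test_random_additive_recovery(self, rep):
        """Additive matrices from random trees (≤ 12 taxa) are reproduced
        exactly by NJ path distances."""
        rng = np.random.default_rng(rep)
        n = int(rng.integers(4, 13))
        ref, _ = synthetic.synth_tree(n_tips=n, seed=int(rng.integers(2**31)))
        d = ref.tip_distance_matrix()
        t = phylo.nj_tree(d)
        d2 = t.tip_distance_matrix()
        assert np.allclose(d.to_numpy(), d2.loc[d.index, d.columns].to_numpy(),
                           atol=1e-8)

    def test_asymmetric_rejected(self):
        import pandas as pd

        d = pd.DataFrame(np.arange(9.0).reshape(3, 3),
                         index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(d)


class TestTreeSimilarity:
    def test_self_is_one(self):
        t, _ = synthetic.synth_tree(n_tips=10, seed=1)
        assert phylo.tree_similarity(t, t).r == pytest.approx(1.0, abs=1e-12)

    def test_uniform_scaling_invariance(self):
        t, _ = synthetic.synth_tree(n_tips=10, seed=2)
        doubled = AnnotatedTree.from_newick(t.to_newick())
        for e in doubled.tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2
        assert phylo.tree_similarity(t, doubled).r == pytest.approx(1.0, abs=1e-12)

    def test_random_pairs_mean_near_zero(self):
        """Independent random 20-tip trees are uncorrelated on average."""
        rs = []
        for seed in range(40):
            a, _ = synthetic.synth_tree(n_tips=20, seed=2 * seed)
            b, _ = synthetic.synth_tree(n_tips=20, seed=2 * seed + 1)
            rs.append(phylo.tree_similarity(a, b).r)
        assert abs(np.mean(rs)) < 0.15

    def test_too_few_shared_tips(self):
        a, _ = synthetic.synth_tree(n_tips=6, seed=3)
        b, _ = synthetic.synth_tree(n_tips=6, seed=4)
        with pytest.raises(ValueError, match="shared tips"):
            phylo.tree_similarity(a, b, pairing={"t0000": "t0000", "t0001": "t0001"})


class TestDiversity:
    def test_cherry(self):
        t = AnnotatedTree.from_newick("((X:0.05,Y:0.05):0.2,(Z:1,W:1):0.2);")
        assert phylo.diversity(t, ["X", "Y"]) == pytest.approx(0.1)

    def test_star_closed_form(self):
        """k tips on a star with equal branches b: every pairwise distance
        (hence the mean) is 2b."""
        t = AnnotatedTree.from_newick("(A:0.3,B:0.3,C:0.3,D:0.3,E:0.3);")
        assert phylo.diversity(t, list("ABCDE")) == pytest.approx(0.6)

    def test_planted_isoform_ordering(self):
        """A distant planted clade has a larger mean tip distance to the
        background clades than the background's internal diversity."""
        spec = [
            {"size": 6, "name": "alphaS", "isoform": "alpha"},
            {"size": 6, "name": "beta", "isoform": "beta"},
            {"size": 6, "name": "gamma", "isoform": "gamma"},
        ]
        t, gt = synthetic.synth_tree(n_tips=18, clade_spec=spec, seed=5, scale=0.2)
        alpha = gt.data["clades"]["alphaS"]
        rest = gt.data["clades"]["beta"] + gt.data["clades"]["gamma"]
        cross = phylo.diversity(t, alpha + rest)
        within = phylo.diversity(t, rest)
        assert cross > within

    def test_missing_tips(self):
        t, _ = synthetic.synth_tree(n_tips=5, seed=6)
        with pytest.raises(KeyError):
            phylo.diversity(t, ["t0000", "zzz"])


class TestCluster:
    def test_identical_merge(self):
        assign, members = phylo.cluster({"a": "AAAA", "b": "AAAA"}, cutoff=0.8)
        assert len(members) == 1

    def test_distant_split(self):
        assign, members = phylo.cluster({"a": "AAAA", "b": "RRNN"}, cutoff=0.8)
        assert len(members) == 2

    def test_greedy_hand_derived(self):
        """Longest-first greedy: s1 (len 10) seeds; s2 joins (0.9 id);
        s3 seeds (0.5 to s1); s4 joins s3; s5 seeds."""
        seqs = {
            "s1": "AAAAAAAAAA",
            "s2": "AAAAAAAAAR",
            "s3": "NNNNNAAAAA",
            "s4": "NNNNNAAAAR",
            "s5": "WWWWWWWWWW",
        }
        assign, members = phylo.cluster(seqs, cutoff=0.8)
        assert assign == {"s1": "s1", "s2": "s1", "s3": "s3", "s4": "s3",
                          "s5": "s5"}

    def test_second_pass_merges_representatives(self):
        seqs = {
            "a": "AAAAAAAAAA",
            "b": "AAAAAAARRR",   # 0.7 to a: separate at 0.8, merges at 0.6
            "c": "WWWWWWWWWW",
        }
        _, members1 = phylo.cluster(seqs, cutoff=0.8)
        assert len(members1) == 3
        _, members2 = phylo.cluster(seqs, cutoff=0.8, then=0.6)
        assert len(members2) == 2

    def test_deterministic(self):
        seqs = {f"s{i}": "AAAAAAAAA" + "ARNDW"[i] for i in range(5)}
        r1 = phylo.cluster(seqs, cutoff=0.8)
        r2 = phylo.cluster(seqs, cutoff=0.8)
        assert r1 == r2


class TestNodeComposition:
    def test_ratio_arithmetic(self):
        spec = [
            {"size": 9, "name": "c0", "n_H": 6, "n_P": 3},
            {"size": 8, "name": "c1", "n_H": 4, "n_P": 4},
            {"size": 8, "name": "c2", "n_H": 4, "n_P": 4},
        ]
        t, gt = synthetic.synth_tree(n_tips=25, clade_spec=spec, seed=7)
        nc = phylo.node_composition(
            t, [gt.data["clades"][f"c{i}"] for i in range(3)],
            clade_names=["c0", "c1", "c2"],
        )
        assert nc.table.set_index("clade").loc["c0", "hp_ratio"] == pytest.approx(2.0)

    def test_all_h_ratio_infinite_excluded(self):
        spec = [
            {"size": 6, "name": "c0", "n_H": 6, "n_P": 0},
            {"size": 6, "name": "c1", "n_H": 3, "n_P": 3},
            {"size": 6, "name": "c2", "n_H": 2, "n_P": 4},
            {"size": 6, "name": "c3", "n_H": 3, "n_P": 3},
        ]
        t, gt = synthetic.synth_tree(n_tips=24, clade_spec=spec, seed=8)
        nc = phylo.node_composition(
            t, [gt.data["clades"][f"c{i}"] for i in range(4)],
            clade_names=[f"c{i}" for i in range(4)],
        )
        tab = nc.table.set_index("clade")
        assert np.isinf(tab.loc["c0", "hp_ratio"])
        assert not tab.loc["c0", "flagged"]

    def test_outlier_clade_flagged(self):
        """One clade at H:P ≈ 5.7 against a background near 1 is flagged by
        the mean ± 2s rule over the other clades."""
        spec = [
            {"size": 20, "name": "hot", "n_H": 17, "n_P": 3},
            {"size": 12, "name": "b1", "n_H": 6, "n_P": 6},
            {"size": 12, "name": "b2", "n_H": 7, "n_P": 5},
            {"size": 12, "name": "b3", "n_H": 5, "n_P": 7},
            {"size": 12, "name": "b4", "n_H": 6, "n_P": 6},
        ]
        t, gt = synthetic.synth_tree(n_tips=68, clade_spec=spec, seed=9)
        names = ["hot", "b1", "b2", "b3", "b4"]
        nc = phylo.node_composition(
            t, [gt.data["clades"][n] for n in names], clade_names=names
        )
        tab = nc.table.set_index("clade")
        assert tab.loc["hot", "flagged"]
        assert not tab.loc[["b1", "b2", "b3", "b4"], "flagged"].any()
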