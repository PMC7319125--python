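"""Tree building, rooting, patristic distances, ultrametricization."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from ribotax.diversification import simulate_yule
from ribotax.io import read_newick
from ribotax.trees import (
    bootstrap_support,
    is_rooted,
    is_ultrametric,
    nj_tree,
    node_depths,
    patristic_distances,
    root_with_outgroup,
    ultrametricize,
)

# additive matrix from the unrooted tree with split AB|CD,
# tip branches A:1, B:2, C:3, D:2 and internal branch 1
ADDITIVE = DistanceMatrix(
    np.array(
        [[0, 3, 5, 4], [3, 0, 6, 5], [5, 6, 0, 5], [4, 5, 5, 0]], dtype=float
    ),
    list("ABCD"),
)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        tree = nj_tree(ADDITIVE)
        got = patristic_distances(tree)
        for a in "ABCD":
            for b in "ABCD":
                assert got[a, b] == pytest.approx(ADDITIVE[a, b], abs=1e-9)
        # the AB|CD split is present
        from ribotax.trees import _bipartitions

        assert frozenset({"A", "B"}) in _bipartitions(tree)

    def test_three_taxa_star(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float), list("ABC")
        )
        tree = nj_tree(dm)
        got = patristic_distances(tree)
        # three-point system has the exact solution
        assert got["A", "B"] == pytest.approx(3)
        assert got["A", "C"] == pytest.approx(4)
        assert got["B", "C"] == pytest.approx(5)

    def test_fewer_than_three_labels_error(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], dtype=float), list("AB"))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_equal_distances_resolved_with_constant_length(self):
        dm = DistanceMatrix(1 - np.eye(5), list("ABCDE"))
        tree = nj_tree(dm)
        assert len(list(tree.tips())) == 5
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert total == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_metrics_recovered(self, seed):
        """NJ is exact on tree metrics: topology and branch lengths."""
        rng = np.random.default_rng(seed)
        tree = simulate_yule(7, seed=seed)
        for node in tree.traverse(include_self=False):
            node.length = float(rng.uniform(0.05, 1.0))
        dm = patristic_distances(tree)
        back = patristic_distances(nj_tree(dm))
        order = list(dm.ids)
        assert np.allclose(
            back.filter(order).data, dm.filter(order).data, atol=1e-9
        )


class TestBootstrap:
    SEQS = {
        "A": "AAAACCCC" * 4,
        "B": "AAAACCCT" * 4,
        "C": "GGGGTTTA" * 4,
        "D": "GGGGTTTT" * 4,
    }

    def test_clean_signal_gives_full_support(self):
        tree = bootstrap_support(self.SEQS, n_replicates=20, seed=0, model="p")
        supports = [
            n.support for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_binary(self):
        tree = bootstrap_support(self.SEQS, n_replicates=1, seed=3, model="p")
        for n in tree.non_tips(include_self=False):
            if getattr(n, "support", None) is not None:
                assert n.support in (0.0, 100.0)

    def test_seed_reproducibility(self):
        t1 = bootstrap_support(self.SEQS, n_replicates=10, seed=5, model="p")
        t2 = bootstrap_support(self.SEQS, n_replicates=10, seed=5, model="p")
        s1 = sorted(
            n.support for n in t1.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        s2 = sorted(
            n.support for n in t2.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        assert s1 == s2

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.SEQS, n_replicates=0, seed=0)


class TestRooting:
    def test_outgroup_rooting_midpoint_of_edge(self):
        tree = read_newick("((A:1,B:2):1,C:1,D:4);")
        rooted = root_with_outgroup(tree, {"D"})
        assert is_rooted(rooted)
        first = sorted(c.name or "" for c in rooted.children)
        assert "D" in first
        # root splits D's 4-unit branch in half
        depths = node_depths(rooted)
        d_tip = next(t for t in rooted.tips() if t.name == "D")
        assert depths[d_tip] == pytest.approx(2.0)

    def test_outgroup_all_tips_error(self):
        tree = read_newick("((A:1,B:2):1,C:1,D:4);")
        with pytest.raises(ValueError):
            root_with_outgroup(tree, {"A", "B", "C", "D"})

    def test_non_separable_outgroup_error(self):
        tree = read_newick("((A:1,B:2):1,(C:1,D:1):1,E:1);")
        with pytest.raises(ValueError, match="separable"):
            root_with_outgroup(tree, {"A", "C"})

    def test_rooting_preserves_bipartitions(self):
        from ribotax.trees import _bipartitions

        tree = read_newick("((A:1,B:2):1,(C:1,D:1):2,E:1);")
        before = _bipartitions(tree)
        rooted = root_with_outgroup(tree, {"E"})
        assert _bipartitions(rooted) == before


class TestPatristic:
    def test_two_tip_path(self):
        tree = read_newick("(A:0.1,B:0.3);")
        assert patristic_distances(tree)["A", "B"] == pytest.approx(0.4)

    def test_zero_lengths_zero_matrix(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        assert patristic_distances(tree).data.max() == 0.0

    def test_missing_length_error(self):
        tree = read_newick("((A:1,B):1,C:1);")
        with pytest.raises(ValueError, match="branch length"):
            patristic_distances(tree)


class TestUltrametricize:
    def test_hand_example_mean_path_length(self):
        # ((A:1,B:3):2,C:4): AB-node age mean(1,3)=2, root age mean(3,5,4)=4
        ultra = ultrametricize(read_newick("((A:1,B:3):2,C:4);"))
        ages = {
            node.name: node.age
            for node in ultra.traverse()
            if node.is_tip()
        }
        assert all(a == 0.0 for a in ages.values())
        internal_ages = sorted(n.age for n in ultra.non_tips(include_self=True))
        assert internal_ages == pytest.approx([0.5, 1.0])
        assert is_ultrametric(ultra)

    def test_already_ultrametric_unchanged(self):
        ultra = ultrametricize(read_newick("((A:1,B:1):1,C:2);"))
        ab = next(n for n in ultra.non_tips(include_self=False))
        assert ab.age == pytest.approx(0.5)

    def test_two_tip_tree(self):
        ultra = ultrametricize(read_newick("(A:1,B:3);"))
        assert ultra.age == 1.0
        assert is_ultrametric(ultra)

    def test_unrooted_input_error(self):
        with pytest.raises(ValueError, match="rooted"):
            ultrametricize(read_newick("(A:1,B:1,C:1);"))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trees_become_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_yule(10, seed=seed)
        for node in tree.traverse(include_self=False):
            node.length = float(rng.uniform(0.01, 1.0))
        ultra = ultrametricize(tree)
        assert is_ultrametric(ultra, rtol=1e-9)
        depths = node_depths(ultra)
        assert max(depths[t] for t in ultra.tips()) == pytest.approx(1.0)
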