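"""NJ and UPGMA construction, rooting, and clock scaling."""

import numpy as np
import pytest

from barcodelim.io import parse_newick
from barcodelim.trees import (
    bipartition_set,
    is_ultrametric,
    nj_tree,
    node_heights,
    root_with_outgroup,
    scale_to_time,
    upgma_tree,
)

from .conftest import make_matrix, path_distance_matrix, random_binary_tree


def tip_edge_lengths(tree):
    return {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}


class TestNJ:
    def test_three_taxon_closed_form(self):
        m = make_matrix(
            ["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]
        )
        tree = nj_tree(m)
        v = tip_edge_lengths(tree)
        assert v["A"] == pytest.approx(0.05)
        assert v["B"] == pytest.approx(0.15)
        assert v["C"] == pytest.approx(0.25)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) as a path-sum matrix
        source = parse_newick("((A:1,B:2):2,(C:3,D:4):0);")
        m = path_distance_matrix(source)
        tree = nj_tree(m)
        assert bipartition_set(tree) == {frozenset({"A", "B"})}
        # all pairwise path lengths reproduced
        rec = path_distance_matrix(tree)
        assert np.allclose(rec.d, m.submatrix(rec.ids).d, atol=1e-9)

    def test_equal_distances_tie_rule_is_deterministic(self):
        m = make_matrix(list("ABCD"), np.ones((4, 4)) - np.eye(4))
        t1 = nj_tree(m)
        t2 = nj_tree(m)
        assert bipartition_set(t1) == bipartition_set(t2)

    def test_na_entries_rejected_with_pair_named(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        m = make_matrix(["x", "y", "z"], d)
        with pytest.raises(ValueError, match="x.*z"):
            nj_tree(m)

    def test_consistency_on_random_additive_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            source = random_binary_tree(int(rng.integers(6, 11)), rng)
            m = path_distance_matrix(source)
            rebuilt = nj_tree(m)
            assert bipartition_set(rebuilt) == bipartition_set(source)
            rec = path_distance_matrix(rebuilt)
            assert np.allclose(rec.d, m.submatrix(rec.ids).d, atol=1e-9)

    def test_agrees_with_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        source = random_binary_tree(8, rng)
        m = path_distance_matrix(source)
        ours = nj_tree(m)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(m.d, ids=m.ids))
        their_splits = set()
        all_tips = frozenset(m.ids)
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            other = all_tips - below
            if len(below) >= 2 and len(other) >= 2:
                their_splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        assert bipartition_set(ours) == their_splits


class TestUPGMA:
    def test_pair_root_height_is_half_distance(self):
        m = make_matrix(["A", "B"], [[0, 0.02], [0.02, 0]])
        tree = upgma_tree(m)
        assert max(node_heights(tree).values()) == pytest.approx(0.01)

    def test_three_taxon_hand_example(self):
        m = make_matrix(
            ["A", "B", "C"], [[0, 0.02, 0.1], [0.02, 0, 0.1], [0.1, 0.1, 0]]
        )
        tree = upgma_tree(m)
        internal = sorted(
            h for n, h in node_heights(tree).items() if not n.is_leaf()
        )
        assert internal == pytest.approx([0.01, 0.05])

    def test_random_matrices_ultrametric_with_monotone_heights(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            d = rng.uniform(0.01, 0.5, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma_tree(make_matrix([f"t{i}" for i in range(n)], d))
            assert is_ultrametric(tree, tol=1e-9)
            heights = node_heights(tree)
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    assert heights[child] <= heights[node] + 1e-12


class TestRooting:
    def test_single_outgroup_tip(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,OG:3):1);")
        tree.is_rooted = False
        rooted = root_with_outgroup(tree, ["OG"])
        sides = [
            sorted(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert ["OG"] in sides

    def test_outgroup_clade_of_two(self):
        tree = parse_newick("(((A:1,B:1):1,C:2):1,(O1:1,O2:1):2);")
        tree.is_rooted = False
        rooted = root_with_outgroup(tree, ["O1", "O2"])
        sides = [
            sorted(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert ["O1", "O2"] in sides
        assert bipartition_set(rooted) >= {frozenset({"O1", "O2"})}

    def test_missing_outgroup_id_raises(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(tree, ["nope"])

    def test_non_monophyletic_outgroup_lists_intruders(self):
        tree = parse_newick("((A:1,O1:1):1,(B:1,O2:1):1);")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="intruding"):
            root_with_outgroup(tree, ["O1", "O2"])


class TestClockScaling:
    def test_paper_calibration_height(self):
        # 1.2% divergence per My: a height of 0.012 subs/site is 1 My
        m = make_matrix(["A", "B"], [[0, 0.024], [0.024, 0]])
        tree = upgma_tree(m)  # root height 0.012
        scaled = scale_to_time(tree, rate=0.012)
        assert max(node_heights(scaled).values()) == pytest.approx(1.0)

    def test_rate_one_is_identity_and_round_trip(self):
        m = make_matrix(
            ["A", "B", "C"], [[0, 0.02, 0.1], [0.02, 0, 0.1], [0.1, 0.1, 0]]
        )
        tree = upgma_tree(m)
        assert max(node_heights(scale_to_time(tree, 1.0)).values()) == pytest.approx(
            max(node_heights(tree).values())
        )
        round_trip = scale_to_time(scale_to_time(tree, 0.012), 1 / 0.012)
        for a, b in zip(
            tree.preorder_edge_iter(), round_trip.preorder_edge_iter()
        ):
            if a.length is not None:
                assert b.length == pytest.approx(a.length, abs=1e-12)

    def test_non_ultrametric_input_rejected(self):
        tree = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            scale_to_time(tree, 0.012)
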