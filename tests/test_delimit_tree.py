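"""Tree-based delimitation: PTP/mPTP search and the GMYC threshold model."""

import math

import numpy as np
import pytest

from barcodelim.delimit_tree import (
    _TreeIndex,
    clusters_at_threshold,
    gmyc_fit,
    lr_test,
    ptp_fit,
    ptp_loglik,
)
from barcodelim.io import parse_newick
from barcodelim.simulate import SimConfig, simulate_trees
from barcodelim.trees import node_heights

from .conftest import random_binary_tree, random_ultrametric_tree


def naive_ptp_loglik(tree, species_tipsets, mode, min_br=1e-4):
    """Independent evaluator: classify each edge by ancestor walking and sum
    per-class exponential profile log-densities at their ML rates."""
    species_tipsets = [frozenset(s) for s in species_tipsets]
    classes = {"spec": [], "coal": {}}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or (node.edge.length or 0.0) < min_br:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        owner = None
        for k, s in enumerate(species_tipsets):
            if tips < s:  # proper subset: edge inside the species subtree
                owner = k
        if owner is None:
            classes["spec"].append(node.edge.length)
        else:
            classes["coal"].setdefault(owner, []).append(node.edge.length)

    def ll(lengths):
        n, s = len(lengths), sum(lengths)
        return 0.0 if n == 0 else n * (math.log(n / s) - 1.0)

    out = ll(classes["spec"])
    if mode == "single":
        pooled = [x for v in classes["coal"].values() for x in v]
        out += ll(pooled)
    else:
        out += sum(ll(v) for v in classes["coal"].values())
    return out


def all_delimitations(idx, v=0):
    out = [[v]]
    if not idx.is_leaf[v]:
        c1, c2 = idx.children[v]
        for a in all_delimitations(idx, c1):
            for b in all_delimitations(idx, c2):
                out.append(a + b)
    return out


class TestPtp:
    def two_clade_tree(self):
        # two 5-tip clades: short within-clade edges, long stems
        def clade(prefix):
            tips = [f"{prefix}{i}:0.002" for i in range(5)]
            s = f"({tips[0]},{tips[1]}):0.002"
            for t in tips[2:]:
                s = f"({s},{t}):0.002"
            return s

        tree = parse_newick(f"({clade('a')}:0.2,{clade('b')}:0.2);")
        tree.is_rooted = True
        return tree

    def test_two_clear_clades_give_two_species(self):
        model, part = ptp_fit(self.two_clade_tree(), mode="single", seed=1)
        assert part.n_otus == 2
        assert model.n_species == 2
        labels = {part.assignment[f"a{i}"] for i in range(5)}
        assert len(labels) == 1

    def test_star_like_tree_prefers_single_species(self):
        # all branch lengths equal: no two-class structure
        tips = [f"t{i}:0.05" for i in range(6)]
        s = f"({tips[0]},{tips[1]}):0.05"
        for t in tips[2:]:
            s = f"({s},{t}):0.05"
        tree = parse_newick(s + ";")
        tree.is_rooted = True
        model, part = ptp_fit(tree, mode="single", seed=1)
        idx = _TreeIndex(tree)
        best = max(
            ptp_loglik(tree, [frozenset(idx.tips_under(r)) for r in roots], "single")
            for roots in all_delimitations(idx)
        )
        assert model.log_likelihood == pytest.approx(best, abs=1e-9)
        assert part.n_otus == 1

    def test_restart_count_does_not_change_optimum(self):
        tree = self.two_clade_tree()
        m0, _ = ptp_fit(tree, mode="single", n_restarts=0, seed=1)
        m10, _ = ptp_fit(tree, mode="single", n_restarts=10, seed=7)
        assert m0.log_likelihood == pytest.approx(m10.log_likelihood, abs=1e-9)

    @pytest.mark.parametrize("mode", ["single", "multi"])
    def test_likelihood_matches_independent_evaluator(self, mode):
        rng = np.random.default_rng(13)
        for _ in range(6):
            tree = random_binary_tree(int(rng.integers(8, 12)), rng)
            idx = _TreeIndex(tree)
            delims = all_delimitations(idx)
            pick = delims[int(rng.integers(0, len(delims)))]
            tipsets = [frozenset(idx.tips_under(r)) for r in pick]
            assert ptp_loglik(tree, tipsets, mode=mode) == pytest.approx(
                naive_ptp_loglik(tree, tipsets, mode), abs=1e-9
            )

    def test_search_never_below_trivial_delimitations(self):
        rng = np.random.default_rng(99)
        tree = random_binary_tree(12, rng)
        idx = _TreeIndex(tree)
        tips = [frozenset([t]) for t in idx.tips_under(0)]
        for mode in ("single", "multi"):
            model, _ = ptp_fit(tree, mode=mode, seed=0)
            assert model.log_likelihood >= ptp_loglik(tree, [frozenset(idx.tips_under(0))], mode) - 1e-9
            assert model.log_likelihood >= ptp_loglik(tree, tips, mode) - 1e-9

    def test_too_few_tips_rejected(self):
        tree = parse_newick("(A:1);")
        with pytest.raises(ValueError):
            ptp_fit(tree)

    def test_all_branches_below_min_br_rejected(self):
        tree = parse_newick("((A:1e-6,B:1e-6):1e-6,C:1e-6);")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="min_br"):
            ptp_fit(tree, min_br=1e-4)


class TestGmyc:
    def five_species_chronogram(self, seed):
        cfg = SimConfig(n_species=5, samples_per_species=6, seed=seed)
        _, gene_tree = simulate_trees(cfg)
        return gene_tree

    def test_recovers_simulated_species(self):
        hits = 0
        for seed in range(1, 11):
            model, part = gmyc_fit(self.five_species_chronogram(seed))
            hits += part.n_otus == 5 and model.p_value < 0.05
        assert hits >= 9  # occasional near-misses tolerated

    def test_single_population_not_systematically_split(self):
        rejections = 0
        for seed in range(1, 21):
            cfg = SimConfig(n_species=1, samples_per_species=15, seed=seed)
            _, gene_tree = simulate_trees(cfg)
            model, _ = gmyc_fit(gene_tree)
            rejections += model.p_value < 0.05
        assert rejections <= 4  # <= 20% at alpha = 0.05

    def test_threshold_boundaries(self):
        rng = np.random.default_rng(8)
        tree = random_ultrametric_tree(9, rng)
        root_h = max(node_heights(tree).values())
        assert clusters_at_threshold(tree, root_h * 1.1).n_otus == 1
        assert clusters_at_threshold(tree, 0.0).n_otus == 9

    def test_lr_nonnegative_and_alt_at_least_null(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            tree = random_ultrametric_tree(int(rng.integers(5, 12)), rng)
            model, _ = gmyc_fit(tree)
            assert model.lr_stat >= 0
            assert model.log_likelihood >= model.null_log_likelihood - 1e-9

    def test_multi_mode_refines_only_with_aic_gain(self):
        tree = self.five_species_chronogram(3)
        single, _ = gmyc_fit(tree, mode="single")
        multi, _ = gmyc_fit(tree, mode="multi")
        assert multi.log_likelihood >= single.log_likelihood - 1e-9
        assert multi.n_clusters >= single.n_clusters

    def test_non_ultrametric_rejected(self):
        tree = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            gmyc_fit(tree)

    def test_too_few_tips_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="3 tips"):
            gmyc_fit(tree)


class TestLrTest:
    def test_equal_likelihoods(self):
        lr, p = lr_test(-10.0, -10.0)
        assert lr == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "lr, expected_p",
        [(5.991, 0.0500116), (0.001, 0.9995001)],  # chi-square df=2 table
    )
    def test_chi_square_table_values(self, lr, expected_p):
        stat, p = lr_test(0.0, lr / 2.0, df=2)
        assert stat == pytest.approx(lr)
        assert p == pytest.approx(expected_p, abs=1e-4)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            lr_test(0.0, 1.0, df=0)
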