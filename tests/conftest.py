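"""Shared fixtures and tree/matrix builders for the test suite."""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.records import BarcodeLibrary, BarcodeRecord
from barcodelim.simulate import SimConfig, make_benchmark

logging.disable(logging.INFO)


def make_matrix(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=list(ids), d=d, n_sites=np.full(d.shape, 100, dtype=int))


def random_binary_tree(n_tips, rng, short=(0.0005, 0.01), long=(0.05, 0.3)):
    """Random rooted binary tree whose branch lengths mix two scales."""

    def draw():
        lo, hi = short if rng.random() < 0.5 else long
        return float(rng.uniform(lo, hi))

    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=f"t{i}")
        nd.edge.length = draw()
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = draw()
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(seed_node=nodes[0], taxon_namespace=tns)
    tree.is_rooted = True
    return tree


def random_ultrametric_tree(n_tips, rng, depth=1.0):
    """Random coalescent-shaped ultrametric tree of given root depth."""
    tns = dendropy.TaxonNamespace()
    active = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=f"t{i}")
        active.append((nd, 0.0))
    t = 0.0
    while len(active) > 1:
        t += float(rng.exponential(1.0 / len(active)))
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        (a, ha), (b, hb) = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - ha
        b.edge.length = t - hb
        active = [p for k, p in enumerate(active) if k not in (i, j)] + [(parent, t)]
    root, height = active[0]
    scale = depth / height
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.is_rooted = True
    return tree


def path_distance_matrix(tree):
    """Tip-to-tip path-length matrix of a tree (the additive oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return make_matrix(ids, d)


@pytest.fixture
def tiny_library():
    return BarcodeLibrary(
        [
            BarcodeRecord("r1", "ATGGCAATGGCA", species_label="spA"),
            BarcodeRecord("r2", "ATGGCAATGGCA", species_label="spA"),
            BarcodeRecord("r3", "ATGGCTATGGCA", species_label="spB"),
        ]
    )


@pytest.fixture(scope="session")
def benchmark():
    """Default 10-species x 10-samples benchmark with known truth."""
    return make_benchmark(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def benchmark_with_outgroup():
    return make_benchmark(SimConfig(seed=2024, outgroup=True))
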