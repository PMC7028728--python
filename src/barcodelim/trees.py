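"""Distance-based trees: neighbor joining, UPGMA, outgroup rooting, clock scaling.

NJ follows the Saitou-Nei recurrences with a fixed tie rule (lowest
``(row, column)`` index pair in the current working-matrix order) so runs are
bit-reproducible; negative branch estimates are clamped to zero with the
deficit moved to the sibling branch, and logged. UPGMA (size-weighted
average linkage) provides the built-in ultrametric stand-in for an
externally inferred chronogram; chronograms can equally be imported as
newick. A strict molecular clock converts ultrametric substitution trees to
time trees (heights / rate).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix

__all__ = [
    "nj_tree",
    "upgma_tree",
    "root_with_outgroup",
    "scale_to_time",
    "node_heights",
    "is_ultrametric",
    "tip_labels",
    "bipartition_set",
]

logger = logging.getLogger(__name__)

ULTRAMETRIC_TOL = 1e-9


def _check_defined(matrix: DistanceMatrix) -> None:
    bad = np.argwhere(np.isnan(matrix.d))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            "distance matrix has undefined entries, e.g. "
            f"({matrix.ids[i]!r}, {matrix.ids[j]!r})"
        )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei) over a fully defined matrix.

    Returns an unrooted tree represented with a trifurcating seed node.
    Q(i,j) = (N-2) d(i,j) - R_i - R_j; the joined pair gets branches
    v_i = d(i,j)/2 + (R_i - R_j)/(2(N-2)), v_j = d(i,j) - v_i; the reduced
    distance is d(u,k) = (d(i,k) + d(j,k) - d(i,j))/2.
    """
    if len(matrix) < 3:
        raise ValueError("nj_tree needs at least 3 taxa")
    _check_defined(matrix)

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for rid in matrix.ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=rid)
        nodes.append(node)
    D = matrix.d.astype(float).copy()

    n_clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: lowest (row, col) among ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        vi = dij / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vj, vi, n_clamped = dij, 0.0, n_clamped + 1
        elif vj < 0.0:
            vi, vj, n_clamped = dij, 0.0, n_clamped + 1
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(vi)
        nodes[j].edge.length = float(vj)
        du = (D[i, :] + D[j, :] - dij) / 2.0
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # final three lineages joined at the central (seed) node
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    va = (dab + dac - dbc) / 2.0
    vb = (dab + dbc - dac) / 2.0
    vc = (dac + dbc - dab) / 2.0
    seed = dendropy.Node()
    for node, v in ((a, va), (b, vb), (c, vc)):
        if v < 0.0:
            n_clamped += 1
            v = 0.0
        seed.add_child(node)
        node.edge.length = float(v)
    if n_clamped:
        logger.info("nj_tree clamped %d negative branch length(s) to 0", n_clamped)

    tree = dendropy.Tree(seed_node=seed, taxon_namespace=tns)
    tree.is_rooted = False
    return tree


def upgma_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Size-weighted average-linkage (classic UPGMA) ultrametric tree.

    Node height = merge distance / 2; clustering is delegated to
    scipy.cluster.hierarchy. The result is rooted and ultrametric.
    """
    if len(matrix) < 2:
        raise ValueError("upgma_tree needs at least 2 taxa")
    _check_defined(matrix)

    tns = dendropy.TaxonNamespace()
    n = len(matrix)
    nodes: dict[int, dendropy.Node] = {}
    heights: dict[int, float] = {}
    for k, rid in enumerate(matrix.ids):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=rid)
        nodes[k] = node
        heights[k] = 0.0

    Z = linkage(squareform(matrix.d, checks=False), method="average")
    for step, (ia, ib, dist, _size) in enumerate(Z):
        parent = dendropy.Node()
        h = float(dist) / 2.0
        for child_idx in (int(ia), int(ib)):
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = max(h - heights[child_idx], 0.0)
        nodes[n + step] = parent
        heights[n + step] = h

    tree = dendropy.Tree(seed_node=nodes[2 * n - 2], taxon_namespace=tns)
    tree.is_rooted = True
    return tree


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of every node above the tips (tips at 0).

    Assumes an ultrametric tree; heights are root-to-tip depth minus
    root-to-node depth.
    """
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] + edge) if parent is not None else 0.0
    total = max(depth[leaf] for leaf in tree.leaf_node_iter())
    return {node: total - d for node, d in depth.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``."""
    depth: dict[dendropy.Node, float] = {}
    tips = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] + edge) if parent is not None else 0.0
        if node.is_leaf():
            tips.append(depth[node])
    return (max(tips) - min(tips)) <= tol


def bipartition_set(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Unrooted bipartitions as canonical frozensets of tip labels.

    Each internal edge is identified by the smaller side of its split
    (ties broken lexicographically); trivial splits are excluded.
    """
    all_tips = frozenset(tip_labels(tree))
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_tips - below
        if len(below) < 2 or len(other) < 2:
            continue
        canon = min(below, other, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_ids: Iterable[str]
) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the ingroup.

    The root is placed at the midpoint of that edge. A non-monophyletic
    outgroup raises with the list of intruding tips.
    """
    outgroup = set(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup_ids must be non-empty")
    tree = tree.clone(depth=1)
    present = set(tip_labels(tree))
    absent = outgroup - present
    if absent:
        raise ValueError(f"outgroup id(s) not in tree: {sorted(absent)}")

    target_edge = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == outgroup or (present - below) == outgroup:
            target_edge = node.edge
            break
    if target_edge is None:
        tree.is_rooted = True  # mrca below is relative to the seed node
        mrca = tree.mrca(taxon_labels=sorted(outgroup))
        under = {l.taxon.label for l in mrca.leaf_iter()}
        intruders = sorted(under - outgroup)
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not monophyletic; intruding tips: {intruders}"
        )

    half = (target_edge.length or 0.0) / 2.0
    tree.reroot_at_edge(target_edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def scale_to_time(tree: dendropy.Tree, rate: float) -> dendropy.Tree:
    """Convert an ultrametric substitution tree to a time tree.

    ``rate`` is the strict-clock rate in substitutions/site per million
    years (e.g. 0.012 for the 1.2%/My COI calibration); all branch lengths
    (hence node heights) are divided by it, topology unchanged.
    """
    if rate <= 0:
        raise ValueError("clock rate must be > 0")
    if not is_ultrametric(tree):
        raise ValueError("scale_to_time requires an ultrametric tree")
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / rate
    return scaled


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Arbitrarily resolve polytomies with zero-length edges (logged)."""
    poly = [
        n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2
    ]
    if poly:
        logger.info("resolving %d polytomy(ies) with zero-length edges", len(poly))
        tree.resolve_polytomies(update_bipartitions=False)
        for edge in tree.preorder_edge_iter():
            if edge.length is None and edge.head_node.parent_node is not None:
                edge.length = 0.0
    return tree
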