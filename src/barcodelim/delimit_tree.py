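"""Tree-based delimitation: Poisson tree processes (PTP/mPTP) and the
general mixed Yule-coalescent model (GMYC/mGMYC).

PTP models branch lengths (substitutions/site) as exponential draws from
two classes. A delimitation is an anti-chain of "species root" nodes
covering all tips: edges inside a species subtree are coalescent-class,
all other edges (those whose parent is ancestral to a species root, plus
the species roots' own stems) are speciation-class. With a class of n
edges of total length S, the maximum-likelihood exponential rate is n/S
and the profile log-likelihood is n ln(n/S) - n. mPTP gives every species
its own coalescent rate. The best delimitation is found by hill climbing
over split/merge moves from both trivial starts plus seeded random
restarts; on small trees this provably matches exhaustive enumeration (see
the test suite).

GMYC operates on an ultrametric chronogram. Nodes older than a threshold T
belong to a Yule diversification process (per-lineage rate lambda_yule);
nodes younger than T are within-species coalescences (Kingman rate
lambda_coal * m(m-1) for a cluster with m lineages). Scaling exponents are
fixed at 1. In this package's formulation each cluster's stem remains a
species-level lineage until the cluster's most recent common ancestor, the
root divergence is conditioned on (no density factor), and both rates have
closed-form ML estimates per threshold, so the threshold is profiled over
internal node heights. The null model (one cluster, pure coalescent) is
the T >= root boundary of the same likelihood, so the likelihood-ratio
statistic is non-negative by construction; its p-value is taken from a
chi-square with (configurably) 2 degrees of freedom. mGMYC greedily
refines single clusters with their own, younger thresholds, accepting a
split when AIC improves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import dendropy
import numpy as np
from scipy.stats import chi2

from .partition import Partition
from .trees import is_ultrametric, node_heights

__all__ = [
    "PtpModel",
    "ptp_fit",
    "GmycModel",
    "gmyc_fit",
    "lr_test",
    "clusters_at_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_BR = 1e-4
_EPS = 1e-12


def lr_test(logl_null: float, logl_alt: float, df: int = 2) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square p-value.

    ``lr = 2 (logl_alt - logl_null)``, clipped at zero to absorb numerical
    jitter (the alternative must not be materially worse than the null).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    if logl_alt < logl_null - 1e-9:
        raise ValueError(
            f"alternative log-likelihood ({logl_alt}) below null ({logl_null})"
        )
    lr = max(2.0 * (logl_alt - logl_null), 0.0)
    return lr, float(chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# shared flat tree index
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Preorder-flattened rooted binary tree with per-node arrays.

    Subtrees occupy contiguous preorder ranges, which makes subtree
    aggregation and anti-chain bookkeeping O(1)/O(subtree).
    """

    def __init__(self, tree: dendropy.Tree, heights: Optional[dict] = None):
        nodes = list(tree.preorder_node_iter())
        self.n = len(nodes)
        self.nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.edge_len = np.zeros(self.n, dtype=float)
        self.is_leaf = np.zeros(self.n, dtype=bool)
        self.label: list[Optional[str]] = [None] * self.n
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_len[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.is_leaf[i] = True
                self.label[i] = nd.taxon.label if nd.taxon else str(i)
        # contiguous subtree range [i, end[i])
        self.end = np.zeros(self.n, dtype=int)
        for i in range(self.n - 1, -1, -1):
            self.end[i] = i + 1 if self.is_leaf[i] else max(
                self.end[c] for c in self.children[i]
            )
        self.n_tips_below = np.zeros(self.n, dtype=int)
        for i in range(self.n - 1, -1, -1):
            self.n_tips_below[i] = (
                1 if self.is_leaf[i] else sum(self.n_tips_below[c] for c in self.children[i])
            )
        if heights is not None:
            self.height = np.array([heights[nd] for nd in nodes], dtype=float)
        else:
            self.height = None

    def tips_under(self, i: int) -> list[str]:
        lo, hi = i, self.end[i]
        return [self.label[k] for k in range(lo, hi) if self.is_leaf[k]]

    def partition_from_roots(self, roots, method: str, params: dict) -> Partition:
        assignment: dict[str, str] = {}
        for r in roots:
            members = self.tips_under(r)
            label = min(members)
            for rid in members:
                assignment[rid] = label
        return Partition(method=method, assignment=assignment, params=params)


def _check_binary(idx: _TreeIndex) -> None:
    bad = [i for i in range(idx.n) if not idx.is_leaf[i] and len(idx.children[i]) != 2]
    if bad:
        raise ValueError(
            "tree must be fully resolved (binary); "
            f"{len(bad)} polytomy/unifurcation node(s) found"
        )


# ---------------------------------------------------------------------------
# PTP / mPTP
# ---------------------------------------------------------------------------


@dataclass
class PtpModel:
    """Fitted Poisson-tree-process model.

    ``lambda_s`` is the speciation-class rate; ``lambda_c`` a single shared
    coalescent rate (mode="single") or a per-species mapping
    (mode="multi"). ``speciation_edge_set`` identifies the species-root
    nodes by their tip sets.
    """

    mode: str
    lambda_s: float
    lambda_c: Union[float, dict[str, float]]
    speciation_edge_set: frozenset
    log_likelihood: float
    min_br: float
    n_species: int = 0


def _class_ll(n: float, s: float) -> float:
    if n == 0:
        return 0.0
    if s <= 0:
        return -math.inf
    return n * (math.log(n / s) - 1.0)


class _PtpState:
    """Anti-chain of species roots with incremental likelihood bookkeeping."""

    def __init__(self, idx: _TreeIndex, mode: str, min_br: float):
        self.idx = idx
        self.mode = mode
        cnt = (idx.edge_len >= min_br) & (idx.parent >= 0)
        self.cnt = cnt.astype(float)
        self.lens = np.where(cnt, idx.edge_len, 0.0)
        # per-node totals over proper descendants' edges
        self.sub_n = np.zeros(idx.n)
        self.sub_s = np.zeros(idx.n)
        for i in range(idx.n - 1, -1, -1):
            for c in idx.children[i]:
                self.sub_n[i] += self.cnt[c] + self.sub_n[c]
                self.sub_s[i] += self.lens[c] + self.sub_s[c]
        self.total_n = self.cnt.sum()
        self.total_s = self.lens.sum()
        # per-node coalescent-class profile term, for O(1) move evaluation
        self.term = np.array(
            [_class_ll(self.sub_n[i], self.sub_s[i]) for i in range(idx.n)]
        )

    def aggregates(self, roots) -> tuple[float, float, float]:
        coal_n = sum(self.sub_n[r] for r in roots)
        coal_s = sum(self.sub_s[r] for r in roots)
        terms = sum(self.term[r] for r in roots)
        return coal_n, coal_s, terms

    def ll_from(self, coal_n: float, coal_s: float, terms: float) -> float:
        spec = _class_ll(self.total_n - coal_n, self.total_s - coal_s)
        if self.mode == "single":
            return spec + _class_ll(coal_n, coal_s)
        return spec + terms

    def loglik(self, roots) -> float:
        return self.ll_from(*self.aggregates(roots))

    def neighbors(self, roots: frozenset):
        """Candidate moves in deterministic preorder order of the acted node."""
        moves = []
        for r in roots:
            if not self.idx.is_leaf[r]:
                moves.append(("split", r))
        for r in roots:
            p = self.idx.parent[r]
            if p >= 0 and all(c in roots for c in self.idx.children[p]):
                moves.append(("merge", p))
        moves.sort(key=lambda m: m[1])
        return moves

    def apply(self, roots: frozenset, move) -> frozenset:
        kind, node = move
        if kind == "split":
            return (roots - {node}) | set(self.idx.children[node])
        return (roots - set(self.idx.children[node])) | {node}


def _hill_climb(state: _PtpState, start: frozenset) -> tuple[frozenset, float]:
    roots = start
    coal_n, coal_s, terms = state.aggregates(roots)
    ll = state.ll_from(coal_n, coal_s, terms)
    cnt, lens, term = state.cnt, state.lens, state.term
    children = state.idx.children
    improved = True
    while improved:
        improved = False
        for kind, node in state.neighbors(roots):
            if kind == "split":
                c1, c2 = children[node]
                dn = -(cnt[c1] + cnt[c2])
                ds = -(lens[c1] + lens[c2])
                dt = term[c1] + term[c2] - term[node]
            else:  # merge at parent `node`
                c1, c2 = children[node]
                dn = cnt[c1] + cnt[c2]
                ds = lens[c1] + lens[c2]
                dt = term[node] - term[c1] - term[c2]
            cand_ll = state.ll_from(coal_n + dn, coal_s + ds, terms + dt)
            if cand_ll > ll + _EPS:
                roots = state.apply(roots, (kind, node))
                coal_n, coal_s, terms = coal_n + dn, coal_s + ds, terms + dt
                ll = cand_ll
                improved = True
                break  # first improvement, deterministic order
    return roots, ll


def _dp_antichain(state: _PtpState, lam_s: float, lam_c: float) -> frozenset:
    """Exact best delimitation for *fixed* class rates.

    With both rates held fixed the objective is a sum of per-edge
    contributions plus (mode="multi") per-species profile terms, so the
    optimal anti-chain decomposes over subtrees and a postorder DP solves
    it exactly. Used as the inner step of coordinate ascent.
    """
    idx = state.idx
    ls = math.log(lam_s) if lam_s > 0 else -math.inf
    lc = math.log(lam_c) if lam_c > 0 else -math.inf
    g = np.zeros(idx.n)
    take = np.zeros(idx.n, dtype=bool)
    for v in range(idx.n - 1, -1, -1):
        if state.mode == "multi":
            a = state.term[v]
        elif state.sub_n[v] == 0:
            a = -lam_c * state.sub_s[v] if lam_c > 0 else 0.0
        else:
            a = state.sub_n[v] * lc - lam_c * state.sub_s[v]
        if idx.is_leaf[v]:
            g[v], take[v] = a, True
            continue
        sp = 0.0
        for c in idx.children[v]:
            edge = (state.cnt[c] * ls if state.cnt[c] else 0.0) - lam_s * state.lens[c]
            sp += edge + g[c]
        if a >= sp:
            g[v], take[v] = a, True
        else:
            g[v], take[v] = sp, False
    roots: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        if take[v]:
            roots.append(v)
        else:
            stack.extend(idx.children[v])
    return frozenset(roots)


def _coordinate_ascent(
    state: _PtpState, roots: frozenset, max_iter: int = 30
) -> tuple[frozenset, float]:
    """Alternate exact DP over delimitations with ML rate updates."""
    ll = state.loglik(roots)
    for _ in range(max_iter):
        coal_n, coal_s, _ = state.aggregates(roots)
        spec_n, spec_s = state.total_n - coal_n, state.total_s - coal_s
        lam_s = spec_n / spec_s if spec_n > 0 else 0.0
        if state.mode == "single":
            lam_c = coal_n / coal_s if coal_n > 0 else 0.0
        else:
            lam_c = 0.0  # unused; per-species terms are pre-profiled
        cand = _dp_antichain(state, lam_s, lam_c)
        cand_ll = state.loglik(cand)
        if cand_ll <= ll + _EPS:
            break
        roots, ll = cand, cand_ll
    return roots, ll


def _random_antichain(idx: _TreeIndex, rng: np.random.Generator) -> frozenset:
    roots: set[int] = set()
    stack = [0]
    while stack:
        v = stack.pop()
        if idx.is_leaf[v] or rng.random() < 0.5:
            roots.add(v)
        else:
            stack.extend(idx.children[v])
    return frozenset(roots)


def _threshold_antichain(idx: _TreeIndex, threshold: float) -> frozenset:
    """Species = maximal subtrees containing no edge >= threshold.

    Long branches read as speciation events; these cuts seed the hill
    climber with the basins a two-class exponential model favours.
    """
    has_long_below = np.zeros(idx.n, dtype=bool)
    for v in range(idx.n - 1, 0, -1):
        p = idx.parent[v]
        if idx.edge_len[v] >= threshold or has_long_below[v]:
            has_long_below[p] = True
    roots: set[int] = set()
    stack = [0]
    while stack:
        v = stack.pop()
        if not has_long_below[v]:
            roots.add(v)
        else:
            stack.extend(idx.children[v])
    return frozenset(roots)


def _threshold_starts(idx: _TreeIndex, max_starts: int = 25) -> list[frozenset]:
    lengths = np.unique(idx.edge_len[idx.parent >= 0])
    lengths = lengths[lengths > 0]
    if lengths.size == 0:
        return []
    cuts = (lengths[:-1] + lengths[1:]) / 2.0 if lengths.size > 1 else lengths
    if cuts.size > max_starts:
        cuts = np.quantile(cuts, np.linspace(0, 1, max_starts))
    seen: set[frozenset] = set()
    out = []
    for thr in cuts:
        chain = _threshold_antichain(idx, float(thr))
        if chain not in seen:
            seen.add(chain)
            out.append(chain)
    return out


def ptp_fit(
    tree: dendropy.Tree,
    mode: str = "single",
    n_restarts: int = 10,
    seed: int = 0,
    min_br: float = DEFAULT_MIN_BR,
) -> tuple[PtpModel, Partition]:
    """Fit PTP (mode="single") or mPTP (mode="multi") on a rooted tree.

    Branch lengths are substitutions/site; edges shorter than ``min_br``
    are excluded from the likelihood. The search runs hill climbing from
    the one-species and all-tips starts plus ``n_restarts`` seeded random
    starts, and returns the best model with its induced partition.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    idx = _TreeIndex(tree)
    n_tips = int(idx.is_leaf.sum())
    if n_tips < 2:
        raise ValueError("ptp_fit needs a tree with at least 2 tips")
    _check_binary(idx)
    if not ((idx.edge_len >= min_br) & (idx.parent >= 0)).any():
        raise ValueError(f"all branch lengths are below min_br={min_br}")

    state = _PtpState(idx, mode, min_br)
    tips = frozenset(np.nonzero(idx.is_leaf)[0].tolist())
    starts = [frozenset({0}), tips]
    starts += _threshold_starts(idx)
    rng = np.random.default_rng(seed)
    starts += [_random_antichain(idx, rng) for _ in range(n_restarts)]

    best_roots, best_ll = None, -math.inf
    for start in starts:
        roots, ll = _hill_climb(state, start)
        roots, ll = _coordinate_ascent(state, roots)
        roots, ll = _hill_climb(state, roots)
        if ll > best_ll + _EPS:
            best_roots, best_ll = roots, ll

    # rate-grid DP seeding: the optimum is a DP fixed point at its own
    # implied speciation rate, so a fine geometric grid over plausible
    # rates plus coordinate ascent recovers narrow basins the move-based
    # climb can miss.
    lengths = state.lens[state.lens > 0]
    if lengths.size:
        lo = 0.1 / float(lengths.max())
        hi = 10.0 / float(lengths.min())
        n_grid = min(int(math.log(hi / lo) / math.log(1.08)) + 2, 250)
        coal_n, coal_s, _ = state.aggregates(best_roots)
        lam_c_seed = coal_n / coal_s if coal_n > 0 else 0.0
        seen: set[frozenset] = set()
        for lam_s in np.geomspace(lo, hi, n_grid):
            cand = _dp_antichain(state, float(lam_s), lam_c_seed)
            if cand in seen:
                continue
            seen.add(cand)
            cand, ll = _coordinate_ascent(state, cand)
            if ll > best_ll + _EPS:
                best_roots, best_ll = cand, ll
        best_roots, best_ll = _hill_climb(state, best_roots)

    roots = sorted(best_roots)
    coal_n = sum(state.sub_n[r] for r in roots)
    coal_s = sum(state.sub_s[r] for r in roots)
    spec_n, spec_s = state.total_n - coal_n, state.total_s - coal_s
    lambda_s = spec_n / spec_s if spec_n > 0 else 0.0
    partition = idx.partition_from_roots(
        roots, method="PTP" if mode == "single" else "mPTP",
        params={"min_br": min_br, "seed": seed, "n_restarts": n_restarts},
    )
    if mode == "single":
        lambda_c: Union[float, dict] = coal_n / coal_s if coal_n > 0 else 0.0
    else:
        lambda_c = {}
        for r in roots:
            label = min(idx.tips_under(r))
            lambda_c[label] = (
                state.sub_n[r] / state.sub_s[r] if state.sub_n[r] > 0 else 0.0
            )
    model = PtpModel(
        mode=mode,
        lambda_s=float(lambda_s),
        lambda_c=lambda_c,
        speciation_edge_set=frozenset(
            frozenset(idx.tips_under(r)) for r in roots
        ),
        log_likelihood=float(best_ll),
        min_br=min_br,
        n_species=len(roots),
    )
    return model, partition


def ptp_loglik(tree: dendropy.Tree, species_roots_tipsets, mode: str = "single",
               min_br: float = DEFAULT_MIN_BR) -> float:
    """Likelihood of an explicit delimitation (species given by tip sets).

    Exposed for cross-checking the search against exhaustive enumeration.
    """
    idx = _TreeIndex(tree)
    state = _PtpState(idx, mode, min_br)
    want = {frozenset(ts) for ts in species_roots_tipsets}
    roots = [
        i for i in range(idx.n) if frozenset(idx.tips_under(i)) in want
    ]
    if len(roots) != len(want):
        raise ValueError("tip sets do not correspond to nodes of the tree")
    return state.loglik(frozenset(roots))


# ---------------------------------------------------------------------------
# GMYC / mGMYC
# ---------------------------------------------------------------------------


@dataclass
class GmycModel:
    """Fitted general mixed Yule-coalescent model.

    ``threshold_T`` is the single threshold age (mode="single") or the
    mapping cluster label -> local threshold age (mode="multi").
    """

    mode: str
    lambda_yule: float
    lambda_coal: float
    threshold_T: Union[float, dict[str, float]]
    n_clusters: int
    log_likelihood: float
    null_log_likelihood: float
    lr_stat: float
    p_value: float
    df: int = 2
    cluster_root_heights: dict[str, float] = field(default_factory=dict)


def _gmyc_coeffs(idx: _TreeIndex, cluster_roots: list[int]):
    """Interval sweep for a cluster-root anti-chain.

    Walking the internal nodes from the root toward the present while
    maintaining k (species-level lineages, cluster stems included down to
    each cluster's MRCA) and B = sum_j m_j(m_j - 1) over clusters, this
    yields, for every inter-event interval, its duration and rate
    coefficients, i.e. everything the waiting-rate b_i = lambda_yule*k_i +
    lambda_coal*B_i needs. Returns ``(k_event, B_event, Y, C)`` where the
    event arrays hold the coefficients of the interval each event closes
    (the root event closes no interval and is conditioned on) and
    Y = sum k_i x_i, C = sum B_i x_i are the total exposures including the
    final interval down to the present.
    """
    in_cluster = np.zeros(idx.n, dtype=bool)
    cl_of = np.full(idx.n, -1)
    root_set = set(cluster_roots)
    for ci, r in enumerate(cluster_roots):
        in_cluster[r : idx.end[r]] = True
        cl_of[r : idx.end[r]] = ci
    internal = np.nonzero(~idx.is_leaf)[0]
    order = internal[np.lexsort((internal, -idx.height[internal]))]
    times = idx.height[order]

    m = np.zeros(len(cluster_roots))
    k = 1.0
    B = 0.0
    k_event, B_event = [], []
    Y = C = 0.0

    def apply(e: int) -> None:
        nonlocal k, B
        if not in_cluster[e]:
            k += 1.0  # speciation: one more species lineage
        elif e in root_set:
            k -= 1.0  # stem ends at the cluster MRCA
            m[cl_of[e]] = 2.0
            B += 2.0
        else:
            c = cl_of[e]
            B += 2.0 * m[c]
            m[c] += 1.0

    apply(order[0])
    for i in range(1, len(order)):
        x = times[i - 1] - times[i]
        Y += k * x
        C += B * x
        k_event.append(k)
        B_event.append(B)
        apply(order[i])
    x = times[-1]  # final interval down to the tips
    Y += k * x
    C += B * x
    return np.array(k_event), np.array(B_event), float(Y), float(C)


def _gmyc_eval(idx: _TreeIndex, cluster_roots: list[int]) -> tuple[float, float, float]:
    """Maximised mixed Yule-coalescent log-likelihood of an anti-chain.

    The likelihood is the waiting-rate (renewal) form: each inter-event
    interval of duration x_i contributes ln(b_i) - b_i x_i with total rate
    b_i = lambda_yule*k_i + lambda_coal*B_i (scaling exponents fixed at 1),
    the root event conditioned on. The two rates are maximised numerically
    (closed form when one class is empty). Returns
    ``(logL, lambda_yule, lambda_coal)``.
    """
    k_e, B_e, Y, C = _gmyc_coeffs(idx, cluster_roots)
    n_e = len(k_e)
    if n_e == 0:
        return 0.0, 0.0, 0.0
    if np.all(B_e == 0) and C == 0:
        # pure Yule: closed-form rate n/Y
        if Y <= 0:
            return -math.inf, 0.0, 0.0
        lam = n_e / Y
        const_k = float(np.sum(np.log(k_e[k_e > 0])))
        return n_e * math.log(lam) + const_k - lam * Y, lam, 0.0
    if np.all(k_e == 0) and Y == 0:
        # pure coalescent (single cluster): closed-form rate n/C
        if C <= 0:
            return -math.inf, 0.0, 0.0
        lam = n_e / C
        const_b = float(np.sum(np.log(B_e[B_e > 0])))
        return n_e * math.log(lam) + const_b - lam * C, 0.0, lam
    if (Y <= 0 and np.any(k_e > 0)) or (C <= 0 and np.any(B_e > 0)):
        return -math.inf, 0.0, 0.0  # degenerate (zero-length) intervals

    def negll(theta: np.ndarray):
        ly, lc = np.exp(theta)
        b = ly * k_e + lc * B_e
        if np.any(b <= 0):
            return np.inf, np.zeros(2)
        f = -float(np.sum(np.log(b))) + ly * Y + lc * C
        gy = ly * (Y - float(np.sum(k_e / b)))
        gc = lc * (C - float(np.sum(B_e / b)))
        return f, np.array([gy, gc])

    from scipy.optimize import minimize

    # warm start from per-class event counts and exposures
    in_cl = np.zeros(idx.n, dtype=bool)
    for r in cluster_roots:
        in_cl[r : idx.end[r]] = True
    n_y = max(int(((~idx.is_leaf) & (~in_cl)).sum()) - 1, 0)
    n_coal = max(n_e - n_y, 1)
    ly0 = max(n_y, 1) / max(Y, 1e-12)
    lc0 = n_coal / max(C, 1e-12)
    best = None
    for start in ((ly0, lc0), (ly0 * 10, lc0), (ly0, lc0 * 10)):
        res = minimize(
            negll,
            np.log(np.maximum(start, 1e-12)),
            jac=True,
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    ly, lc = np.exp(best.x)
    return -float(best.fun), float(ly), float(lc)


def _roots_for_rank(idx: _TreeIndex, order: np.ndarray, j: int) -> list[int]:
    """Cluster roots when the oldest ``j`` internal nodes are speciation."""
    if j == 0:
        return [0]
    spec = np.zeros(idx.n, dtype=bool)
    spec[order[:j]] = True
    roots = []
    for i in range(idx.n):
        p = idx.parent[i]
        if not spec[i] and p >= 0 and spec[p]:
            roots.append(i)
    return roots


def clusters_at_threshold(tree: dendropy.Tree, threshold: float) -> Partition:
    """Clusters induced by an explicit threshold age.

    Cluster roots are the first nodes younger than or at ``threshold`` on
    each root-to-tip path; a threshold at or above the root height yields a
    single cluster, a threshold of zero yields one cluster per tip.
    """
    heights = node_heights(tree)
    idx = _TreeIndex(tree, heights)
    spec = (~idx.is_leaf) & (idx.height > threshold)
    if not spec[0]:
        roots = [0]
    else:
        roots = [
            i
            for i in range(idx.n)
            if not spec[i] and idx.parent[i] >= 0 and spec[idx.parent[i]]
        ]
    return idx.partition_from_roots(
        roots, method="threshold", params={"threshold": threshold}
    )


def gmyc_fit(
    chronogram: dendropy.Tree,
    mode: str = "single",
    df: int = 2,
) -> tuple[GmycModel, Partition]:
    """Fit GMYC (mode="single") or mGMYC (mode="multi") on a chronogram.

    The single threshold is profiled over internal node heights with
    closed-form rate estimates; mode="multi" then greedily splits single
    clusters at their own local thresholds while AIC improves. The reported
    p-value compares the fitted model against the one-cluster coalescent
    null via a chi-square likelihood-ratio test.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    tips = [l for l in chronogram.leaf_node_iter()]
    if len(tips) < 3:
        raise ValueError("gmyc_fit needs a chronogram with at least 3 tips")
    if not is_ultrametric(chronogram, tol=1e-6 * max(
        1.0, max(node_heights(chronogram).values())
    )):
        raise ValueError("gmyc_fit requires an ultrametric chronogram")
    heights = node_heights(chronogram)
    idx = _TreeIndex(chronogram, heights)
    _check_binary(idx)

    internal = np.nonzero(~idx.is_leaf)[0]
    # stable: oldest first, parents before equal-height children (preorder)
    order = internal[np.lexsort((internal, -idx.height[internal]))]
    n_int = len(order)

    null_ll, _, _ = _gmyc_eval(idx, [0])
    best = (null_ll, 0, [0])
    for j in range(1, n_int + 1):
        roots = _roots_for_rank(idx, order, j)
        ll, _, _ = _gmyc_eval(idx, roots)
        if ll > best[0] + _EPS:
            best = (ll, j, roots)
    best_ll, best_j, roots = best
    threshold = float(idx.height[order[best_j]]) if best_j < n_int else 0.0

    aic_splits = 0
    if mode == "multi":
        current_ll = best_ll
        improved = True
        while improved:
            improved = False
            for r in sorted(roots):
                if idx.is_leaf[r]:
                    continue
                cand = sorted(set(roots) - {r}) + idx.children[r]
                cand_ll, _, _ = _gmyc_eval(idx, cand)
                if cand_ll > current_ll + 1.0:  # one extra threshold parameter
                    roots = cand
                    current_ll = cand_ll
                    aic_splits += 1
                    improved = True
                    break
        best_ll = current_ll

    final_ll, lam_y, lam_c = _gmyc_eval(idx, roots)
    lr, p = lr_test(null_ll, final_ll, df=df)
    partition = idx.partition_from_roots(
        roots,
        method="GMYC" if mode == "single" else "mGMYC",
        params={"df": df},
    )
    root_heights = {
        min(idx.tips_under(r)): float(idx.height[r]) for r in roots
    }
    threshold_T: Union[float, dict[str, float]]
    if mode == "single":
        threshold_T = threshold
    else:
        threshold_T = dict(root_heights)
    model = GmycModel(
        mode=mode,
        lambda_yule=float(lam_y),
        lambda_coal=float(lam_c),
        threshold_T=threshold_T,
        n_clusters=len(roots),
        log_likelihood=float(final_ll),
        null_log_likelihood=float(null_ll),
        lr_stat=float(lr),
        p_value=float(p),
        df=df,
        cluster_root_heights=root_heights,
    )
    return model, partition
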