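"""Synthetic barcode libraries with known truth.

The generator emulates the statistical structure a multi-species COI
barcode library is assumed to have: a Yule (pure-birth) species tree, a
multispecies-coalescent gene genealogy within it (simulated with msprime),
and K2P sequence evolution along the gene tree at 651 bp under a strict
molecular clock. Every simulated record carries its true species label, so
each downstream stage can be scored against a ground-truth partition.

Units: species and gene trees are simulated in time (My) and converted to
substitutions/site through ``clock_rate`` (default 0.012/My, the 1.2%/My
COI calibration); divergence knobs (``coal_depth_mean``,
``min_split_depth``) are stated in substitutions/site so they compare
directly with K2P distances.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import msprime
import numpy as np
from dendropy.simulate import treesim

from .io import write_library, write_newick
from .partition import Partition
from .records import BarcodeLibrary, BarcodeRecord

__all__ = ["SimConfig", "SimTruth", "simulate_trees", "evolve_sequences", "make_benchmark"]

# decoding table matching the distance module's encoding (A=0,G=1,C=2,T=3)
_BASES = np.array(list("AGCT"))
# vertebrate-mito stop codons in code space: TAA, TAG, AGA, AGG
_STOP_CODONS = {(3, 0, 0), (3, 0, 1), (0, 1, 0), (0, 1, 1)}

OUTGROUP_SPECIES = "outgroup"


@dataclass
class SimConfig:
    """Study conditions for one synthetic barcode library.

    ``coal_depth_mean`` is the expected within-species TMRCA in
    substitutions/site (the 0.002 default keeps maximum intraspecific
    divergence in the 0.5-1% range, well below the split-depth floor);
    ``min_split_depth`` is a floor on species split depths
    (substitutions/site) that keeps species distinct molecular lineages
    (minimum interspecific divergence ~2x the floor); ``yule_rate`` (per
    My) sets the depth of the rest of the species tree (~10% interspecific
    divergence at the defaults); ``kappa`` is the transition/transversion
    rate ratio of the K2P substitution process.
    """

    n_species: int = 10
    samples_per_species: Union[int, list[int]] = 10
    yule_rate: float = 0.46
    coal_depth_mean: float = 0.002
    min_split_depth: float = 0.02
    seq_length: int = 651
    kappa: float = 4.0
    clock_rate: float = 0.012
    seed: int = 1
    outgroup: bool = False
    orf_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name in ("yule_rate", "coal_depth_mean", "seq_length", "kappa", "clock_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_split_depth < 0:
            raise ValueError("min_split_depth must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        ks = self.samples_list()
        if len(ks) != self.n_species or any(k < 1 for k in ks):
            raise ValueError("samples_per_species must be positive, one per species")

    def samples_list(self) -> list[int]:
        if isinstance(self.samples_per_species, int):
            return [self.samples_per_species] * self.n_species
        return list(self.samples_per_species)

    def species_names(self) -> list[str]:
        width = max(2, len(str(self.n_species)))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]


@dataclass
class SimTruth:
    """Ground truth attached to a simulated library."""

    true_partition: Partition
    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree

    def pair_class(self, id_a: str, id_b: str) -> str:
        """Expected divergence class of a record pair: "intra" or "inter"."""
        a = self.true_partition.assignment[id_a]
        b = self.true_partition.assignment[id_b]
        return "intra" if a == b else "inter"


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def _species_ages(config: SimConfig, rng: random.Random) -> tuple[dendropy.Tree, dict]:
    """Yule species tree (time units: My) with a terminal-branch floor."""
    floor_my = config.min_split_depth / config.clock_rate
    names = config.species_names()
    if config.n_species == 1:
        tns = dendropy.TaxonNamespace()
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=names[0])
        tree = dendropy.Tree(seed_node=node, taxon_namespace=tns)
        tree.is_rooted = True
        return tree, {}
    tree = treesim.birth_death_tree(
        birth_rate=config.yule_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    # the simulator stops at the n-th birth, leaving the youngest split at
    # age 0; continue the memoryless pure-birth process to a random
    # inspection time before the next speciation
    extra = rng.expovariate(config.yule_rate * config.n_species)
    for leaf, name in zip(tree.leaf_node_iter(), names):
        leaf.taxon.label = name
        leaf.edge.length = (leaf.edge.length or 0.0) + floor_my + extra
    return tree, _node_ages(tree)


def _node_ages(tree: dendropy.Tree) -> dict:
    depth: dict = {}
    for node in tree.preorder_node_iter():
        p = node.parent_node
        depth[node] = (depth[p] + (node.edge.length or 0.0)) if p else 0.0
    total = max(depth[l] for l in tree.leaf_node_iter())
    return {node: total - d for node, d in depth.items()}


def _demography(
    config: SimConfig, species_tree: dendropy.Tree, ages: dict
) -> tuple[msprime.Demography, float]:
    """msprime demography mirroring the species tree (times in My)."""
    pop_size = config.coal_depth_mean / config.clock_rate / 2.0
    dem = msprime.Demography()
    pop_name: dict = {}
    n_anc = 0
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
        else:
            name = f"anc_{n_anc}"
            n_anc += 1
        pop_name[node] = name
        dem.add_population(name=name, initial_size=pop_size)
    for node in species_tree.postorder_node_iter():
        if not node.is_leaf():
            dem.add_population_split(
                time=ages[node],
                derived=[pop_name[c] for c in node.child_nodes()],
                ancestral=pop_name[node],
            )
    root = species_tree.seed_node
    root_age = ages.get(root, 0.0)
    if config.outgroup:
        floor_my = config.min_split_depth / config.clock_rate
        og_age = root_age * 1.5 + floor_my
        dem.add_population(name=OUTGROUP_SPECIES, initial_size=pop_size)
        dem.add_population(name="anc_root", initial_size=pop_size)
        dem.add_population_split(
            time=og_age,
            derived=[pop_name[root], OUTGROUP_SPECIES],
            ancestral="anc_root",
        )
        root_age = og_age
    dem.sort_events()
    return dem, root_age


def simulate_trees(config: SimConfig) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Yule species tree plus multispecies-coalescent gene tree.

    Both trees carry branch lengths in substitutions/site (time x clock
    rate). Gene-tree tips are the simulated records, named
    ``<species>_s<k>``; the same seed always returns identical trees.
    """
    seeds = _subseeds(config.seed, 3)
    species_tree, ages = _species_ages(config, random.Random(seeds[0]))
    dem, _ = _demography(config, species_tree, ages)

    names = config.species_names()
    sample_sets = []
    record_ids: list[str] = []
    for name, k in zip(names, config.samples_list()):
        sample_sets.append(msprime.SampleSet(k, population=name, ploidy=1))
        record_ids += [f"{name}_s{i + 1:02d}" for i in range(k)]
    if config.outgroup:
        sample_sets.append(
            msprime.SampleSet(1, population=OUTGROUP_SPECIES, ploidy=1)
        )
        record_ids.append(f"{OUTGROUP_SPECIES}_s01")

    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        ploidy=1,
        random_seed=seeds[1],
    )
    gtree = ts.first()

    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for u in gtree.nodes(order="preorder"):
        node = dendropy.Node()
        parent = gtree.parent(u)
        if parent != -1:
            nodes[parent].add_child(node)
            node.edge.length = gtree.branch_length(u) * config.clock_rate
        nodes[u] = node
    for u in ts.samples():
        nodes[u].taxon = tns.new_taxon(label=record_ids[u])
    gene_tree = dendropy.Tree(seed_node=nodes[gtree.root], taxon_namespace=tns)
    gene_tree.is_rooted = True

    # species tree in substitution units as well
    for edge in species_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * config.clock_rate
    return species_tree, gene_tree


def _draw_root(rng: np.random.Generator, length: int, orf_mode: bool) -> np.ndarray:
    seq = rng.integers(0, 4, size=length).astype(np.int8)
    if orf_mode:
        for start in range(0, length - 2, 3):
            while tuple(seq[start : start + 3]) in _STOP_CODONS:
                seq[start : start + 3] = rng.integers(0, 4, size=3)
    return seq


def _fix_stops(child: np.ndarray, parent: np.ndarray) -> None:
    for start in range(0, len(child) - 2, 3):
        if tuple(child[start : start + 3]) in _STOP_CODONS:
            child[start : start + 3] = parent[start : start + 3]


def evolve_sequences(gene_tree: dendropy.Tree, config: SimConfig) -> BarcodeLibrary:
    """Evolve sequences along a gene tree under the K2P substitution model.

    Branch lengths are expected substitutions/site; the transition
    probability per branch follows the K80 closed form with rate ratio
    ``kappa``. The root sequence is uniform over A,C,G,T per site; in
    ``orf_mode`` substitutions creating vertebrate-mito stop codons in
    frame 1 are rejected so the library passes the stop-codon screen.
    """
    rng = np.random.default_rng(_subseeds(config.seed, 3)[2])
    L = config.seq_length
    kappa = config.kappa
    seqs: dict = {}
    root = gene_tree.seed_node
    seqs[root] = _draw_root(rng, L, config.orf_mode)
    for node in gene_tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = seqs[node.parent_node]
        b = node.edge.length or 0.0
        if b <= 0:
            child = parent_seq.copy()
        else:
            at = kappa * b / (kappa + 2.0)
            bt = b / (kappa + 2.0)
            p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
            p_tv = 0.25 - 0.25 * np.exp(-4.0 * bt)
            u = rng.random(L)
            child = parent_seq.copy()
            p_same = 1.0 - p_ts - 2.0 * p_tv
            child[(u >= p_same) & (u < p_same + p_ts)] ^= 1
            child[(u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)] ^= 2
            child[u >= p_same + p_ts + p_tv] ^= 3
            if config.orf_mode:
                _fix_stops(child, parent_seq)
        seqs[node] = child

    records = []
    for leaf in gene_tree.leaf_node_iter():
        rid = leaf.taxon.label
        species = rid.rsplit("_s", 1)[0]
        records.append(
            BarcodeRecord(
                record_id=rid,
                sequence="".join(_BASES[seqs[leaf]]),
                species_label=species,
                source="generated",
            )
        )
    records.sort(key=lambda r: r.record_id)
    return BarcodeLibrary(records)


def make_benchmark(
    config: SimConfig, out_dir: Optional[Union[str, Path]] = None
) -> tuple[BarcodeLibrary, SimTruth]:
    """One-call benchmark: library + truth, optionally written to disk.

    When ``out_dir`` is given, writes ``library.fasta``, ``metadata.tsv``,
    ``gene_tree.nwk``, ``species_tree.nwk`` and ``truth.tsv``.
    """
    species_tree, gene_tree = simulate_trees(config)
    library = evolve_sequences(gene_tree, config)
    assignment = {r.record_id: r.species_label for r in library}
    truth = SimTruth(
        true_partition=Partition(
            method="truth", assignment=assignment, params={"seed": config.seed}
        ),
        species_tree=species_tree,
        gene_tree=gene_tree,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_library(library, out / "library.fasta", out / "metadata.tsv")
        write_newick(gene_tree, out / "gene_tree.nwk")
        write_newick(species_tree, out / "species_tree.nwk")
        truth.true_partition.write_tsv(out / "truth.tsv")
    return library, truth
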