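"""End-to-end delimitation pipeline.

Workflow: QC (length filter, stop-codon screen) -> haplotype pruning ->
K2P distances -> NJ tree (rooted) and UPGMA chronogram -> the requested
delimitation methods -> 50% majority consensus -> barcoding-gap analytics
and the split-species report.

Haplotype pruning applies to the delimitation inputs only; distance
statistics are computed on the full post-QC library, and OTU labels are
propagated from haplotype representatives back to all members. The whole
pipeline is a pure function of (inputs, config, seed): rerunning with the
same seed writes byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import qc
from .consensus import (
    consensus_partition,
    gap_stats,
    otus_per_species_counts,
    species_otu_table,
)
from .delimit_distance import AbgdConfig, abgd_partition, resl_like, select_abgd_partition
from .delimit_tree import gmyc_fit, ptp_fit
from .distances import pairwise_matrix
from .io import read_library, write_newick
from .partition import Partition
from .records import BarcodeLibrary
from .trees import nj_tree, root_with_outgroup, upgma_tree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("resl", "abgd", "ptp", "mptp", "gmyc", "mgmyc")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Provide either ``library`` (in memory) or ``fasta``/``metadata`` paths.
    ``methods`` defaults to all six delimiters; ``outgroup_ids`` roots the
    NJ tree (midpoint rooting when empty).
    """

    library: Optional[BarcodeLibrary] = None
    fasta: Optional[str] = None
    metadata: Optional[str] = None
    min_len: int = qc.DEFAULT_MIN_LEN
    methods: Sequence[str] = KNOWN_METHODS
    outgroup_ids: Sequence[str] = ()
    quorum: float = 0.5
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    resl_threshold: float = 0.022
    min_br: float = 1e-4
    n_restarts: int = 2
    seed: int = 1
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; choose from {KNOWN_METHODS}")
        if not (0 < self.quorum <= 1):
            raise ValueError("quorum must be in (0, 1]")
        if self.library is None and self.fasta is None:
            raise ValueError("provide a library or a fasta path")


@dataclass
class PipelineResult:
    """All artifacts of one run, plus a JSON-ready summary."""

    library: BarcodeLibrary
    qc_reports: dict
    haplotype_members: dict
    matrix: object
    nj: object
    chronogram: object
    partitions: dict[str, Partition]
    consensus: object
    gap_species: object
    gap_otu: object
    split_table: object
    summary: dict


def _stage(name):
    """Wrap stage errors with the stage name for actionable failures."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full delimitation workflow and return all artifacts."""
    with _stage("load"):
        library = config.library or read_library(config.fasta, config.metadata)

    with _stage("qc"):
        library, length_report = qc.length_filter(library, config.min_len)
        stop_report = qc.stop_codon_screen(library)
        reps, members_of = qc.collapse_haplotypes(library)

    with _stage("distances"):
        matrix = pairwise_matrix(library)
        rep_matrix = matrix.submatrix(reps.ids)

    nj = chrono = None
    need_nj = {"ptp", "mptp"} & set(config.methods)
    need_chrono = {"gmyc", "mgmyc"} & set(config.methods)
    with _stage("trees"):
        if need_nj:
            nj = nj_tree(rep_matrix)
            present_og = [i for i in config.outgroup_ids if i in reps]
            if present_og:
                nj = root_with_outgroup(nj, present_og)
            else:
                nj.reroot_at_midpoint(update_bipartitions=False)
                nj.is_rooted = True
        if need_chrono:
            chrono = upgma_tree(rep_matrix)

    partitions: dict[str, Partition] = {}
    models: dict[str, object] = {}
    with _stage("delimitation"):
        for method in config.methods:
            if method == "resl":
                part = resl_like(rep_matrix, threshold=config.resl_threshold)
            elif method == "abgd":
                part = select_abgd_partition(abgd_partition(rep_matrix, config.abgd))
            elif method in ("ptp", "mptp"):
                model, part = ptp_fit(
                    nj,
                    mode="single" if method == "ptp" else "multi",
                    n_restarts=config.n_restarts,
                    seed=config.seed,
                    min_br=config.min_br,
                )
                models[method] = model
            else:  # gmyc / mgmyc
                model, part = gmyc_fit(
                    chrono, mode="single" if method == "gmyc" else "multi"
                )
                models[method] = model
            partitions[method] = part.propagate(members_of).relabeled()

    with _stage("consensus"):
        cons = consensus_partition(list(partitions.values()), quorum=config.quorum)

    species_labels = library.species_labels()
    have_species = len(set(species_labels.values()) - {"unknown"}) >= 2
    gap_sp = gap_otu = split_table = None
    with _stage("report"):
        if have_species:
            gap_sp = gap_stats(matrix, species_labels, level="species")
        if cons.consensus.n_otus >= 2:
            gap_otu = gap_stats(matrix, cons.consensus.assignment, level="otu")
        if have_species and cons.consensus.n_otus >= 2:
            split_table = species_otu_table(cons.consensus, species_labels, matrix)

    summary = {
        "n_records": len(library),
        "n_haplotypes": len(reps),
        "alignment_length": library.alignment_length,
        "qc": {
            "n_input": length_report.n_input,
            "n_passed_length": length_report.n_passed_length,
            "min_len": length_report.min_len,
            "max_len": length_report.max_len,
            "n_stop_codon_flagged": stop_report.n_stop_codon_flagged,
        },
        "otu_counts": {m: partitions[m].n_otus for m in config.methods},
        "consensus_otus": cons.consensus.n_otus,
        "quorum": config.quorum,
        "seed": config.seed,
        "gap": {
            "species_ratio_of_means": getattr(gap_sp, "ratio_of_means", None),
            "species_overlap": getattr(gap_sp, "overlap_exists", None),
            "otu_ratio_of_means": getattr(gap_otu, "ratio_of_means", None),
            "otu_mean_of_ratios": getattr(gap_otu, "mean_of_ratios", None),
            "otu_overlap": getattr(gap_otu, "overlap_exists", None),
        },
    }
    if have_species:
        summary["species_by_n_otus"] = {
            str(k): int(v)
            for k, v in otus_per_species_counts(
                cons.consensus, species_labels
            ).items()
        }

    result = PipelineResult(
        library=library,
        qc_reports={"length": length_report, "stop_codon": stop_report},
        haplotype_members=members_of,
        matrix=matrix,
        nj=nj,
        chronogram=chrono,
        partitions=partitions,
        consensus=cons,
        gap_species=gap_sp,
        gap_otu=gap_otu,
        split_table=split_table,
        summary=summary,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.write_tsv(out / "k2p_matrix.tsv")
    if result.nj is not None:
        write_newick(result.nj, out / "nj_tree.nwk")
    if result.chronogram is not None:
        write_newick(result.chronogram, out / "upgma_chronogram.nwk")
    for method, part in result.partitions.items():
        part.write_tsv(out / f"partition_{method}.tsv")
    result.consensus.consensus.write_tsv(out / "partition_consensus.tsv")
    if result.split_table is not None:
        result.split_table.to_csv(out / "species_otu_table.tsv", sep="\t", index=False)
    for level, gaps in (("species", result.gap_species), ("otu", result.gap_otu)):
        if gaps is not None:
            gaps.to_frame().to_csv(out / f"gap_{level}.tsv", sep="\t", index=False)
            gaps.histogram.to_csv(out / f"gap_{level}_hist.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
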