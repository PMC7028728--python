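"""Majority consensus over delimitation partitions and barcoding-gap analytics.

The consensus rule is a pairwise quorum graph: ``co_assignment(i, j)`` is
the fraction of input partitions that place records i and j in the same
OTU; the consensus OTUs are the connected components of the graph with an
edge wherever that fraction reaches the quorum (default 0.5). Components
held together only by chains of above-quorum pairs (some pair inside below
quorum) are logged, so transitive merges are auditable.

Barcoding-gap analytics summarise, per group (morphological species or
consensus OTU), the maximum intraspecific distance and the nearest-neighbor
distance, the two published fold-ratio readings (ratio of means and mean of
per-group ratios), a per-group overlap flag, and histogram-ready binned
distributions (1% bins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, GroupDistStats, group_stats
from .partition import Partition

__all__ = [
    "ConsensusResult",
    "consensus_partition",
    "GapStats",
    "gap_stats",
    "species_otu_table",
    "otus_per_species_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Consensus partition plus the co-assignment evidence behind it."""

    input_methods: list[str]
    ids: list[str]
    co_assignment: np.ndarray
    consensus: Partition
    transitive_components: list[str] = field(default_factory=list)

    @property
    def n_otus(self) -> int:
        return self.consensus.n_otus


def consensus_partition(
    partitions: Sequence[Partition], quorum: float = 0.5
) -> ConsensusResult:
    """Quorum-graph consensus of >= 1 partitions over one id set.

    Records are co-assigned in the consensus when the fraction of input
    partitions agreeing reaches ``quorum``; OTUs are the connected
    components of that relation. Partitions over mismatched id sets raise.
    """
    if not partitions:
        raise ValueError("need at least one input partition")
    if not (0 < quorum <= 1):
        raise ValueError("quorum must be in (0, 1]")
    ids = sorted(partitions[0].ids)
    for p in partitions[1:]:
        if sorted(p.ids) != ids:
            raise ValueError(
                f"partition {p.method!r} covers a different id set"
            )
    n = len(ids)
    co = np.zeros((n, n))
    for p in partitions:
        codes, seen = [], {}
        for rid in ids:
            label = p.assignment[rid]
            codes.append(seen.setdefault(label, len(seen)))
        arr = np.asarray(codes)
        co += (arr[:, None] == arr[None, :]).astype(float)
    co /= len(partitions)

    adj = co >= quorum
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)

    transitive = []
    for c in set(comp):
        members = np.nonzero(comp == c)[0]
        if len(members) > 1 and co[np.ix_(members, members)].min() < quorum:
            label = min(ids[m] for m in members)
            transitive.append(label)
            logger.warning(
                "consensus component %r held together only transitively", label
            )

    assignment = {rid: str(c) for rid, c in zip(ids, comp)}
    consensus = Partition(
        method="consensus",
        assignment=assignment,
        params={
            "quorum": quorum,
            "input_methods": [p.method for p in partitions],
        },
    ).relabeled()
    return ConsensusResult(
        input_methods=[p.method for p in partitions],
        ids=ids,
        co_assignment=co,
        consensus=consensus,
        transitive_components=sorted(transitive),
    )


@dataclass
class GapStats:
    """Barcoding-gap summary at one grouping level.

    ``ratio_of_means`` = mean(nearest-neighbor) / mean(max-intra over
    non-singleton groups); ``mean_of_ratios`` averages per-group
    nn/max-intra over groups whose max-intra is defined and positive.
    Singletons contribute to the nearest-neighbor mean only.
    """

    level: str
    per_group: list[GroupDistStats]
    overlap_exists: bool
    ratio_of_means: float
    mean_of_ratios: float
    histogram: pd.DataFrame

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        f = 100.0 if percent else 1.0
        return pd.DataFrame(
            [
                {
                    "group": s.group_label,
                    "n": s.n_members,
                    "max_intra": s.max_intra * f,
                    "nn_dist": s.nn_dist * f,
                    "nn_label": s.nn_label,
                    "overlap": (
                        not math.isnan(s.max_intra) and s.max_intra > s.nn_dist
                    ),
                }
                for s in self.per_group
            ]
        )


def _histogram(stats: list[GroupDistStats], bin_width_pct: float = 1.0) -> pd.DataFrame:
    """Per-bin counts of max-intra and nearest-neighbor distances (percent)."""
    intra = [s.max_intra * 100 for s in stats if not math.isnan(s.max_intra)]
    nn = [s.nn_dist * 100 for s in stats if not math.isnan(s.nn_dist)]
    top = max(intra + nn, default=0.0)
    edges = np.arange(0.0, top + 2 * bin_width_pct, bin_width_pct)
    ci, _ = np.histogram(intra, bins=edges)
    cn, _ = np.histogram(nn, bins=edges)
    return pd.DataFrame(
        {
            "bin_low_pct": edges[:-1],
            "bin_high_pct": edges[1:],
            "max_intra_count": ci,
            "nn_count": cn,
        }
    )


def gap_stats(
    matrix: DistanceMatrix, labels: Mapping[str, str], level: str
) -> GapStats:
    """Barcoding-gap summary for a grouping of the distance matrix.

    ``level`` names the grouping ("species" or "otu"). Requires >= 2
    groups; if every group is a singleton both ratios are NaN.
    """
    if level not in ("species", "otu"):
        raise ValueError("level must be 'species' or 'otu'")
    stats = group_stats(matrix, labels)
    intra = np.array(
        [s.max_intra for s in stats if not math.isnan(s.max_intra)]
    )
    nn = np.array([s.nn_dist for s in stats if not math.isnan(s.nn_dist)])
    if intra.size == 0:
        logger.warning("all groups are singletons; gap ratios undefined")
        rom = mor = math.nan
    else:
        rom = float(nn.mean() / intra.mean()) if intra.mean() > 0 else math.nan
        ratios = [
            s.nn_dist / s.max_intra
            for s in stats
            if not math.isnan(s.max_intra) and s.max_intra > 0
            and not math.isnan(s.nn_dist)
        ]
        mor = float(np.mean(ratios)) if ratios else math.nan
    overlap = any(
        not math.isnan(s.max_intra) and s.max_intra > s.nn_dist for s in stats
    )
    return GapStats(
        level=level,
        per_group=stats,
        overlap_exists=overlap,
        ratio_of_means=rom,
        mean_of_ratios=mor,
        histogram=_histogram(stats),
    )


def species_otu_table(
    consensus: Partition,
    species_labels: Mapping[str, str],
    matrix: DistanceMatrix,
) -> pd.DataFrame:
    """Report table of morphological species split into more than one OTU.

    One row per such species (max-intra and nearest-neighbor distance at
    species level, percent) followed by one sub-row per OTU it contains
    (OTU-level distances; NA max-intra for singleton OTUs). Species with a
    single OTU are excluded.
    """
    ids = [i for i in matrix.ids if i in consensus.assignment]
    if set(ids) != set(matrix.ids):
        matrix = matrix.submatrix(ids)
    sp_stats = {
        s.group_label: s for s in group_stats(matrix, dict(species_labels))
    }
    otu_labels = {rid: consensus.assignment[rid] for rid in matrix.ids}
    otu_stats = {s.group_label: s for s in group_stats(matrix, otu_labels)}

    otus_of_species: dict[str, list[str]] = {}
    for rid in matrix.ids:
        otus_of_species.setdefault(species_labels[rid], [])
        otu = otu_labels[rid]
        if otu not in otus_of_species[species_labels[rid]]:
            otus_of_species[species_labels[rid]].append(otu)

    rows = []
    for species in sorted(otus_of_species):
        otus = sorted(otus_of_species[species])
        if len(otus) < 2:
            continue
        s = sp_stats[species]
        rows.append(
            {
                "species": species,
                "otu": "",
                "n": s.n_members,
                "max_intra_pct": round(s.max_intra * 100, 2),
                "nn_pct": round(s.nn_dist * 100, 2),
            }
        )
        for otu in otus:
            o = otu_stats[otu]
            rows.append(
                {
                    "species": species,
                    "otu": otu,
                    "n": o.n_members,
                    "max_intra_pct": (
                        float("nan")
                        if math.isnan(o.max_intra)
                        else round(o.max_intra * 100, 2)
                    ),
                    "nn_pct": round(o.nn_dist * 100, 2),
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "otu", "n", "max_intra_pct", "nn_pct"]
    )


def otus_per_species_counts(
    consensus: Partition, species_labels: Mapping[str, str]
) -> pd.Series:
    """Number of species having k consensus OTUs, for each observed k."""
    otus_of_species: dict[str, set[str]] = {}
    for rid, otu in consensus.assignment.items():
        otus_of_species.setdefault(species_labels[rid], set()).add(otu)
    counts = pd.Series(
        [len(v) for v in otus_of_species.values()], dtype=int
    ).value_counts().sort_index()
    counts.index.name = "n_otus"
    counts.name = "n_species"
    return counts
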