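"""Kimura two-parameter (K2P) distances and per-group distance statistics.

The K2P model corrects observed transition (P) and transversion (Q)
proportions for multiple hits::

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Comparisons use pairwise deletion: a site enters a pair's comparison only
when both sequences carry an unambiguous base (A, C, G or T). IUPAC
ambiguity codes, N and gaps are treated as missing. Pairs whose corrected
distance is undefined (no comparable sites, or a log of a non-positive
argument, i.e. saturation) are reported as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import BarcodeLibrary

__all__ = [
    "k2p_distance",
    "pairwise_matrix",
    "DistanceMatrix",
    "GroupDistStats",
    "group_stats",
]

logger = logging.getLogger(__name__)

# Base encoding chosen so that a transition flips the low bit:
# A=0, G=1 (purines), C=2, T=3 (pyrimidines); anything else is missing.
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lower case
_MISSING = 255


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (255 = missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(n_sites: int, n_ts: int, n_tv: int) -> float:
    if n_sites == 0:
        return math.nan
    p = n_ts / n_sites
    q = n_tv / n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance between two equal-length aligned sequences.

    Returns ``(distance, n_sites)`` where ``n_sites`` counts positions at
    which both sequences carry an unambiguous base. The distance is NaN when
    undefined (zero comparable sites) or saturated.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    both = (a != _MISSING) & (b != _MISSING)
    n = int(both.sum())
    if n == 0:
        return math.nan, 0
    diff = both & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())  # same purine/pyrimidine class
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(n, ts, tv), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix with comparable-site counts.

    ``d`` holds distances in substitutions/site (NaN where undefined or
    saturated); ``n_sites`` the per-pair count of compared positions.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shapes must match the id list")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            n_sites=self.n_sites[np.ix_(idx, idx)].copy(),
        )

    @property
    def n_saturated_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.d[iu]).sum())

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        """Square DataFrame; ``percent=True`` reports distances x100, the
        scale used in user-facing tables."""
        d = self.d * 100.0 if percent else self.d
        return pd.DataFrame(d, index=self.ids, columns=self.ids)

    def write_tsv(self, path, percent: bool = False) -> None:
        self.to_dataframe(percent=percent).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d = df.to_numpy(dtype=float)
        return cls(ids=[str(i) for i in df.index], d=d, n_sites=np.zeros_like(d, dtype=int))


def pairwise_matrix(library: BarcodeLibrary) -> DistanceMatrix:
    """All-pairs K2P distances for a library (pairwise deletion).

    Logs the count of saturated/undefined pairs. Requires >= 2 records.
    """
    if len(library) < 2:
        raise ValueError("pairwise_matrix needs at least 2 records")
    ids = library.ids
    n = len(ids)
    codes = np.stack([encode_sequence(r.sequence) for r in library])
    present = codes != _MISSING
    klass = codes >> 1  # purine/pyrimidine class; junk for missing, masked below

    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, present.sum(axis=1))
    for i in range(n - 1):
        both = present[i] & present[i + 1 :]
        diff = both & (codes[i] != codes[i + 1 :])
        ts = (diff & (klass[i] == klass[i + 1 :])).sum(axis=1)
        nd = diff.sum(axis=1)
        ns = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ns > 0, ts / np.maximum(ns, 1), np.nan)
            q = np.where(ns > 0, (nd - ts) / np.maximum(ns, 1), np.nan)
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            dij = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.maximum(w1, 1e-300))
                - 0.25 * np.log(np.maximum(w2, 1e-300)),
                np.nan,
            )
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
        sites[i, i + 1 :] = ns
        sites[i + 1 :, i] = ns

    matrix = DistanceMatrix(ids=ids, d=d, n_sites=sites)
    if matrix.n_saturated_pairs:
        logger.warning(
            "%d pair(s) saturated or undefined in K2P matrix",
            matrix.n_saturated_pairs,
        )
    return matrix


@dataclass
class GroupDistStats:
    """Distance summaries for one group (species or OTU).

    ``max_intra`` is the largest within-group distance, NaN exactly for
    singletons; ``nn_dist`` the minimum distance from any member to any
    non-member, ``nn_label`` that neighbor's group.
    """

    group_label: str
    n_members: int
    max_intra: float
    nn_dist: float
    nn_label: Optional[str]


def group_stats(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> list[GroupDistStats]:
    """Per-group maximum-intraspecific and nearest-neighbor distances.

    Saturated (NaN) pairs are excluded with a warning. Raises if any id is
    unlabelled or if there is only one group (nearest neighbor undefined).
    """
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise KeyError(f"unlabelled ids: {missing}")
    lab = np.array([labels[i] for i in matrix.ids])
    groups = sorted(set(lab))
    if len(groups) < 2:
        raise ValueError("group_stats needs at least 2 groups (nearest neighbor undefined)")
    if np.isnan(matrix.d[np.triu_indices(len(matrix), k=1)]).any():
        logger.warning("saturated pairs excluded from group statistics")

    out: list[GroupDistStats] = []
    for g in groups:
        inside = lab == g
        dg = matrix.d[inside][:, inside]
        iu = np.triu_indices(dg.shape[0], k=1)
        intra = dg[iu]
        intra = intra[~np.isnan(intra)]
        max_intra = float(intra.max()) if intra.size else math.nan
        between = matrix.d[inside][:, ~inside]
        other_labels = lab[~inside]
        if np.isnan(between).all():
            nn_dist, nn_label = math.nan, None
        else:
            j = int(np.nanargmin(np.nanmin(between, axis=0)))
            nn_dist = float(np.nanmin(between))
            nn_label = str(other_labels[j])
        out.append(
            GroupDistStats(
                group_label=g,
                n_members=int(inside.sum()),
                max_intra=max_intra,
                nn_dist=nn_dist,
                nn_label=nn_label,
            )
        )
    return out


def group_stats_table(stats: list[GroupDistStats], percent: bool = True) -> pd.DataFrame:
    """Tabular view of :func:`group_stats`; percent scale by default."""
    f = 100.0 if percent else 1.0
    return pd.DataFrame(
        [
            {
                "group": s.group_label,
                "n": s.n_members,
                "max_intra": s.max_intra * f,
                "nn_dist": s.nn_dist * f,
                "nn_label": s.nn_label,
            }
            for s in stats
        ]
    )
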