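"""Core data model: barcode records, libraries, and QC reports.

A *barcode record* is one aligned COI sequence plus its taxonomic and
geographic metadata; a *library* is an ordered collection of records that
share one alignment coordinate system (equal-length aligned sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = ["BarcodeRecord", "BarcodeLibrary", "QcReport", "GAP_CHARS"]

#: Characters treated as alignment gaps (not counted toward sequence length).
GAP_CHARS = frozenset("-.")

_VALID_SOURCES = ("generated", "mined")


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its metadata.

    Parameters
    ----------
    record_id:
        Unique identifier within a library.
    sequence:
        Aligned nucleotide string over ``A,C,G,T,-,N`` and IUPAC ambiguity
        codes (case-insensitive; stored upper-case).
    species_label:
        Morphological species assignment; ``"unknown"`` when missing.
    site_id, region:
        Optional sampling-site and island/region identifiers.
    source:
        ``"generated"`` (newly produced) or ``"mined"`` (repository record).
    """

    record_id: str
    sequence: str
    species_label: str = "unknown"
    site_id: Optional[str] = None
    region: Optional[str] = None
    source: str = "generated"

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: sequence must be non-empty")
        if self.source not in _VALID_SOURCES:
            raise ValueError(
                f"record {self.record_id!r}: source must be one of {_VALID_SOURCES}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def ungapped_length(self) -> int:
        """Sequence length counted over non-gap characters."""
        return sum(1 for c in self.sequence if c not in GAP_CHARS)

    @property
    def ungapped_sequence(self) -> str:
        return "".join(c for c in self.sequence if c not in GAP_CHARS)


class BarcodeLibrary:
    """An ordered collection of aligned :class:`BarcodeRecord` objects.

    All sequences must have equal (aligned) length and unique ids.
    """

    def __init__(self, records: Sequence[BarcodeRecord]):
        records = list(records)
        lengths = {len(r.sequence) for r in records} or {0}
        if len(lengths) != 1:
            raise ValueError(
                f"aligned sequences must share one length; found {sorted(lengths)}"
            )
        seen = set()
        for r in records:
            if r.record_id in seen:
                raise ValueError(f"duplicate record_id {r.record_id!r}")
            seen.add(r.record_id)
        self._records = records
        self._index = {r.record_id: r for r in records}
        self.alignment_length: int = lengths.pop()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> BarcodeRecord:
        return self._index[record_id]

    @property
    def records(self) -> list[BarcodeRecord]:
        return list(self._records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self._records]

    def species_labels(self) -> dict[str, str]:
        """Mapping record_id -> morphological species label."""
        return {r.record_id: r.species_label for r in self._records}

    def subset(self, ids: Sequence[str]) -> "BarcodeLibrary":
        """New library restricted to ``ids``, keeping this library's order."""
        keep = set(ids)
        missing = keep - set(self._index)
        if missing:
            raise KeyError(f"ids not in library: {sorted(missing)}")
        return BarcodeLibrary([r for r in self._records if r.record_id in keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BarcodeLibrary(n={len(self)}, alignment_length={self.alignment_length})"
        )


@dataclass
class QcReport:
    """Outcome of a computational QC step over a library.

    ``flagged_ids`` lists records that failed the step; ``reasons`` gives a
    short machine-readable reason per flagged record.
    """

    n_input: int
    n_passed_length: int = 0
    n_stop_codon_flagged: int = 0
    min_len: int = 0
    max_len: int = 0
    flagged_ids: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_passed_length > self.n_input:
            raise ValueError("n_passed_length cannot exceed n_input")
        if len(self.flagged_ids) > self.n_input:
            raise ValueError("more flagged ids than input records")
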