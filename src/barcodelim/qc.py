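"""Computational QC: length filtering, stop-codon screening, haplotype collapsing.

These are the in-silico checks applied to a COI barcode library before
distance and delimitation analyses: a minimum ungapped-length filter, a
vertebrate-mitochondrial stop-codon screen (a functional COI fragment has an
open reading frame in at least one forward frame), and collapsing of
byte-identical aligned haplotypes.
"""

from __future__ import annotations

import logging

from Bio.Data import CodonTable

from .records import BarcodeLibrary, BarcodeRecord, QcReport

__all__ = ["length_filter", "stop_codon_screen", "collapse_haplotypes"]

logger = logging.getLogger(__name__)

#: Stop codons of the vertebrate mitochondrial code (NCBI table 2):
#: TAA, TAG, AGA, AGG.
VERTEBRATE_MITO_STOPS = frozenset(
    CodonTable.unambiguous_dna_by_id[2].stop_codons
)

#: Default minimum ungapped length (bp). Real COI barcodes in reference
#: libraries run roughly 459-651 bp; 400 keeps every plausible record.
DEFAULT_MIN_LEN = 400


def length_filter(
    library: BarcodeLibrary, min_len: int = DEFAULT_MIN_LEN
) -> tuple[BarcodeLibrary, QcReport]:
    """Drop records whose ungapped length is below ``min_len``.

    Returns the filtered library (order preserved) and a QC report with the
    observed ungapped length range and the flagged ids. An empty result is
    allowed and logged, not an error.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    lengths = {r.record_id: r.ungapped_length for r in library}
    kept = [r.record_id for r in library if lengths[r.record_id] >= min_len]
    flagged = [rid for rid, ln in lengths.items() if ln < min_len]
    report = QcReport(
        n_input=len(library),
        n_passed_length=len(kept),
        min_len=min(lengths.values(), default=0),
        max_len=max(lengths.values(), default=0),
        flagged_ids=flagged,
        reasons={rid: "below_min_len" for rid in flagged},
    )
    if not kept:
        logger.warning("length_filter(min_len=%d) removed every record", min_len)
    return library.subset(kept), report


def stop_codon_screen(library: BarcodeLibrary, code: str = "vertebrate_mito") -> QcReport:
    """Screen each record for internal stop codons.

    The ungapped sequence is translated conceptually in all three forward
    frames; a record passes if at least one frame contains no stop codon of
    the vertebrate mitochondrial code. Codons containing ambiguity codes are
    not counted as stops. Sequences shorter than one codon are flagged with
    reason ``"too_short"``.
    """
    if code != "vertebrate_mito":
        raise ValueError(f"unsupported genetic code {code!r}")
    flagged: list[str] = []
    reasons: dict[str, str] = {}
    for rec in library:
        seq = rec.ungapped_sequence
        if len(seq) < 3:
            flagged.append(rec.record_id)
            reasons[rec.record_id] = "too_short"
            continue
        if not any(_frame_is_open(seq, f) for f in range(3)):
            flagged.append(rec.record_id)
            reasons[rec.record_id] = "stop_codons_all_frames"
    n_stop = sum(1 for r in reasons.values() if r != "too_short")
    if flagged:
        logger.warning("stop_codon_screen flagged %d record(s)", len(flagged))
    lengths = [r.ungapped_length for r in library]
    return QcReport(
        n_input=len(library),
        n_passed_length=len(library),
        n_stop_codon_flagged=n_stop,
        min_len=min(lengths, default=0),
        max_len=max(lengths, default=0),
        flagged_ids=flagged,
        reasons=reasons,
    )


def _frame_is_open(seq: str, frame: int) -> bool:
    """True if no complete codon in this forward frame is a stop codon.

    The barcode fragment sits mid-gene, so every complete codon is treated
    as internal; a trailing partial codon is ignored.
    """
    for i in range(frame, len(seq) - 2, 3):
        if seq[i : i + 3] in VERTEBRATE_MITO_STOPS:
            return False
    return True


def collapse_haplotypes(
    library: BarcodeLibrary,
) -> tuple[BarcodeLibrary, dict[str, list[str]]]:
    """Collapse byte-identical aligned sequences to one representative each.

    Identity is exact string equality on the aligned sequence, gaps and
    ambiguity codes included (so sequences differing only by an ``N`` are
    *not* collapsed). The representative is the first record in input order;
    the returned mapping ``representative_id -> member_ids`` is a partition
    of all input ids (members listed in input order, representative first).
    """
    members: dict[str, list[str]] = {}
    rep_of_seq: dict[str, str] = {}
    for rec in library:
        rep = rep_of_seq.get(rec.sequence)
        if rep is None:
            rep_of_seq[rec.sequence] = rec.record_id
            members[rec.record_id] = [rec.record_id]
        else:
            members[rep].append(rec.record_id)
    collapsed = library.subset(list(members))
    if len(collapsed) < len(library):
        logger.info(
            "collapsed %d records to %d unique haplotypes",
            len(library),
            len(collapsed),
        )
    return collapsed, members
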