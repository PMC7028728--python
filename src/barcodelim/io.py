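"""File I/O: FASTA libraries with TSV metadata, and newick trees.

The on-disk formats are the field's plain-text standards: aligned FASTA for
sequences, a UTF-8 tab-separated metadata table with a header row and
required columns ``record_id`` and ``species_label`` (extra columns are
preserved verbatim), and newick for trees.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from .records import BarcodeLibrary, BarcodeRecord

__all__ = [
    "read_library",
    "write_library",
    "read_metadata",
    "read_newick",
    "write_newick",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]

REQUIRED_METADATA_COLUMNS = ("record_id", "species_label")


def read_metadata(metadata_path: PathLike) -> pd.DataFrame:
    """Read a tab-separated metadata table keyed by ``record_id``.

    Requires columns ``record_id`` and ``species_label``; any further
    columns are carried through untouched.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, encoding="utf-8")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(
            f"metadata table {metadata_path} lacks required column(s): {missing}"
        )
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_id(s) in metadata: {dups}")
    return meta


def read_library(
    fasta_path: PathLike, metadata_path: Optional[PathLike] = None
) -> BarcodeLibrary:
    """Read an aligned FASTA plus optional TSV metadata into a library.

    One record per FASTA entry, in file order. Entries absent from the
    metadata table are kept with ``species_label="unknown"`` and a logged
    warning; duplicated FASTA ids are an error.
    """
    meta_by_id: dict[str, dict] = {}
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        meta_by_id = {
            row["record_id"]: row.to_dict() for _, row in meta.iterrows()
        }

    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {fasta_path}")
        seen.add(rid)
        row = meta_by_id.get(rid)
        if row is None:
            if metadata_path is not None:
                logger.warning(
                    "record %r has no metadata row; species_label set to 'unknown'",
                    rid,
                )
            row = {}

        def _get(key: str) -> Optional[str]:
            val = row.get(key)
            if val is None or (isinstance(val, float) and pd.isna(val)):
                return None
            return str(val)

        records.append(
            BarcodeRecord(
                record_id=rid,
                sequence=str(entry.seq),
                species_label=_get("species_label") or "unknown",
                site_id=_get("site_id"),
                region=_get("region"),
                source=_get("source") or "generated",
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return BarcodeLibrary(records)


def write_library(
    library: BarcodeLibrary, fasta_path: PathLike, metadata_path: Optional[PathLike] = None
) -> None:
    """Write a library back to aligned FASTA (and optionally TSV metadata)."""
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for rec in library:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")
    if metadata_path is not None:
        rows = [
            {
                "record_id": r.record_id,
                "species_label": r.species_label,
                "site_id": r.site_id,
                "region": r.region,
                "source": r.source,
            }
            for r in library
        ]
        pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_newick(path: PathLike) -> dendropy.Tree:
    """Read one newick tree; malformed input raises ``ValueError`` with the
    parser's position information."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string (same conventions as :func:`read_newick`)."""
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Canonical newick string with branch lengths at 10 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    """Write a tree as newick; round-trips topology, labels and branch
    lengths to 10 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree_to_newick(tree) + "\n")
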