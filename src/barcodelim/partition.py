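"""OTU partitions: the common result type of every delimitation method."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

__all__ = ["Partition", "labels_from_groups"]


@dataclass
class Partition:
    """A total assignment of record ids to OTU labels, with provenance.

    ``assignment`` maps every record id to exactly one OTU label;
    ``method`` and ``params`` record how the partition was produced.
    """

    method: str
    assignment: dict[str, str]
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("a Partition must assign at least one id")

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def groups(self) -> dict[str, list[str]]:
        """OTU label -> member ids (members in assignment order)."""
        out: dict[str, list[str]] = {}
        for rid, label in self.assignment.items():
            out.setdefault(label, []).append(rid)
        return out

    def relabeled(self) -> "Partition":
        """Canonical labels: each OTU named after its lexicographically
        smallest member id."""
        groups = self.groups()
        new = {}
        for members in groups.values():
            label = min(members)
            for rid in members:
                new[rid] = label
        return Partition(method=self.method, assignment=new, params=dict(self.params))

    def propagate(self, members_of: Mapping[str, list[str]]) -> "Partition":
        """Extend a partition of haplotype representatives to all members.

        ``members_of`` maps each representative id (present in this
        partition) to the records it stands for.
        """
        new: dict[str, str] = {}
        for rep, label in self.assignment.items():
            for rid in members_of.get(rep, [rep]):
                new[rid] = label
        return Partition(method=self.method, assignment=new, params=dict(self.params))

    def same_otu(self, id_a: str, id_b: str) -> bool:
        return self.assignment[id_a] == self.assignment[id_b]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": list(self.assignment),
                "otu_label": list(self.assignment.values()),
                "method": self.method,
                "params": repr(self.params),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def labels_from_groups(groups: Mapping[str, list[str]]) -> dict[str, str]:
    """Invert a label -> members mapping to id -> label."""
    out: dict[str, str] = {}
    for label, members in groups.items():
        for rid in members:
            out[rid] = label
    return out
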