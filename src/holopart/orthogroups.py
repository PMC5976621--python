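"""Ortholog-group filtering and taxon-set (Venn) partitioning.

Groups come from an OrthoMCL-style clustering consumed as a membership
table.  After dropping groups with fewer than three members, each group
is assigned to exactly one taxon subset — the exact set of taxa with at
least one member — giving the Venn counts that summarise shared and
lineage-specific gene families (e.g. octocoral-only vs shared with
scleractinians).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["OrthoGroupTable", "filter_min_members", "venn_partition"]

DEFAULT_TAXA = ("Hcoe", "Gven", "Scleractinia")


class ConsistencyError(ValueError):
    pass


@dataclass
class OrthoGroupTable:
    """group_id -> (taxon -> member count)."""

    groups: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable) -> "OrthoGroupTable":
        groups: dict[str, dict[str, int]] = {}
        for group_id, taxon, _member in rows:
            per_taxon = groups.setdefault(group_id, {})
            per_taxon[taxon] = per_taxon.get(taxon, 0) + 1
        return cls(groups=groups)

    def total_members(self, group_id: str) -> int:
        return sum(self.groups[group_id].values())

    def __len__(self) -> int:
        return len(self.groups)


def filter_min_members(table: OrthoGroupTable,
                       min_members: int = 3) -> OrthoGroupTable:
    """Keep groups with at least ``min_members`` members in total."""
    kept = {g: dict(counts) for g, counts in table.groups.items()
            if sum(counts.values()) >= min_members}
    return OrthoGroupTable(groups=kept)


def venn_partition(
    table: OrthoGroupTable,
    taxa: tuple[str, ...] = DEFAULT_TAXA,
) -> dict[frozenset, list[str]]:
    """Partition groups by the exact set of taxa with >= 1 member.

    Returns subset -> sorted group ids; each group appears in exactly
    one subset, so subset sizes sum to the table size.  Only presence
    matters — member-count magnitudes never change the partition.
    """
    universe = set(taxa)
    out: dict[frozenset, list[str]] = {}
    for group_id, counts in table.groups.items():
        present = {t for t, n in counts.items() if n >= 1}
        unknown = present - universe
        if unknown:
            raise ConsistencyError(
                f"group {group_id!r} names unknown taxa {sorted(unknown)}")
        out.setdefault(frozenset(present), []).append(group_id)
    for ids in out.values():
        ids.sort()
    return out


def venn_counts(table: OrthoGroupTable,
                taxa: tuple[str, ...] = DEFAULT_TAXA) -> dict[frozenset, int]:
    """Subset -> number of groups (convenience over :func:`venn_partition`)."""
    return {s: len(g) for s, g in venn_partition(table, taxa).items()}
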