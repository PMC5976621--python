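"""KEGG metabolic-complementation analysis.

For each KEGG pathway (a set of KO enzyme identifiers), computes the
percentage of enzymes represented by transcripts from each origin bin.
A pathway whose enzymes are split between host-only and symbiont-only
representation is evidence of metabolic interdependency within the
holobiont — e.g. amino-acid synthesis enzymes present only in symbiont
transcripts suggest the host relies on its symbionts for those amino
acids.

Category rules per enzyme: present in both host and symbiont bins ->
"both" (regardless of the specific bin); otherwise host or symbiont
alone; "specific" only when neither host nor symbiont carries it;
absent everywhere -> "unrepresented".  Only presence matters — extra
transcripts per KO never change a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PathwayDef",
    "PathwayCoverage",
    "CATEGORIES",
    "build_ko2bin",
    "enzyme_category",
    "pathway_coverage",
    "key_enzyme_report",
]

CATEGORIES = ("host", "symbiont", "both", "specific", "unrepresented")
_VALID_BINS = {"host", "symbiont", "specific"}


class ConsistencyError(ValueError):
    pass


@dataclass
class PathwayDef:
    pathway_id: str
    name: str
    ko_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ko_ids)) != len(self.ko_ids):
            raise ValueError(
                f"pathway {self.pathway_id!r} lists duplicate KO ids")


@dataclass
class PathwayCoverage:
    pathway_id: str
    n_ko: int
    pct_host: float
    pct_symbiont: float
    pct_both: float
    pct_specific: float
    pct_unrepresented: float


def build_ko2bin(
    assignments: Mapping[str, str],
    ko_map: pd.DataFrame | Iterable[tuple[str, str]],
) -> dict[str, set[str]]:
    """KO -> set of bins holding >= 1 transcript annotated with that KO."""
    if not isinstance(ko_map, pd.DataFrame):
        ko_map = pd.DataFrame(list(ko_map), columns=["member_id", "term_id"])
    out: dict[str, set[str]] = {}
    for row in ko_map.itertuples(index=False):
        b = assignments.get(row.member_id)
        if b is None:
            continue
        out.setdefault(row.term_id, set()).add(b)
    return out


def enzyme_category(ko_id: str, ko2bin: Mapping[str, set[str]]) -> str:
    """Category of one enzyme from the bins that carry it."""
    bins = ko2bin.get(ko_id, set())
    unknown = bins - _VALID_BINS
    if unknown:
        raise ConsistencyError(
            f"KO {ko_id!r} mapped to unknown bin(s) {sorted(unknown)}")
    if "host" in bins and "symbiont" in bins:
        return "both"
    if "host" in bins:
        return "host"
    if "symbiont" in bins:
        return "symbiont"
    if "specific" in bins:
        return "specific"
    return "unrepresented"


def pathway_coverage(
    pathway: PathwayDef,
    ko2bin: Mapping[str, set[str]],
) -> PathwayCoverage:
    """Percentage of the pathway's enzymes in each category.

    The denominator is every KO in the pathway definition, with the
    unrepresented remainder explicit, so the five percentages always sum
    to 100 as exact rationals.
    """
    if not pathway.ko_ids:
        raise ValueError(f"pathway {pathway.pathway_id!r} has no KOs")
    tally = dict.fromkeys(CATEGORIES, 0)
    for ko in pathway.ko_ids:
        tally[enzyme_category(ko, ko2bin)] += 1
    n = len(pathway.ko_ids)
    pct = {c: 100.0 * tally[c] / n for c in CATEGORIES}
    return PathwayCoverage(
        pathway_id=pathway.pathway_id, n_ko=n,
        pct_host=pct["host"], pct_symbiont=pct["symbiont"],
        pct_both=pct["both"], pct_specific=pct["specific"],
        pct_unrepresented=pct["unrepresented"],
    )


def key_enzyme_report(
    enzymes: Mapping[str, str] | Sequence[tuple[str, str]],
    ko2bin: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Presence per bin for named key enzymes.

    ``enzymes`` maps KO id -> human-readable enzyme name.  The
    ``symbiont_not_host`` flag marks enzymes present in symbiont
    transcripts but absent from host transcripts — the signature of a
    biosynthetic step the host depends on its symbionts for.
    """
    items = (enzymes.items() if isinstance(enzymes, Mapping)
             else list(enzymes))
    rows = []
    for ko, name in items:
        bins = ko2bin.get(ko, set())
        rows.append((
            ko, name, "host" in bins, "symbiont" in bins,
            "specific" in bins,
            ("symbiont" in bins) and ("host" not in bins),
        ))
    return pd.DataFrame(rows, columns=[
        "ko_id", "name", "in_host", "in_symbiont", "in_specific",
        "symbiont_not_host",
    ])
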