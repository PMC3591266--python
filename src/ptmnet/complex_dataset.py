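"""Protein-complex membership and per-complex modification statistics.

Complexes are consumed from a tab-delimited table of member identifier sets
(emulating a ConsensusPathDB-style export, including "family expanded"
variants that differ only in which paralog fills one slot). Filtering keeps
complexes of at least three unique subunits and collapses each family group
onto its most highly modified variant. Per complex and PTM type the two
summary coordinates of the enrichment analysis are the *total* (sum over
members of per-member record counts) and the *median* member count, with
unmodified or unknown members contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median as _median

import pandas as pd

from .ptm_dataset import PTM_TYPES, PTMDataset


@dataclass(frozen=True)
class ProteinComplex:
    complex_id: str
    members: frozenset[str]
    family_group: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ComplexStats:
    complex_id: str
    ptm_type: str
    total: int
    median: float
    n_members: int


@dataclass
class ComplexParseResult:
    complexes: list[ProteinComplex] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def parse_complexes(path: str) -> ComplexParseResult:
    """Read a complex table: complex_id <TAB> member;member;... [<TAB> family_group].

    Duplicate members within a row are collapsed (and flagged in the log); rows
    with an empty member field are rejected. Complexes with exactly identical
    member sets are merged onto the smallest complex_id.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "complex_id" not in table.columns or "members" not in table.columns:
        raise ValueError("complex table requires columns: complex_id, members[, family_group]")
    has_family = "family_group" in table.columns

    result = ComplexParseResult()
    parsed: list[ProteinComplex] = []
    for row in table.itertuples(index=False):
        raw = [m for m in row.members.split(";") if m]
        if not raw:
            result.log.append(f"reject complex {row.complex_id}: empty member field")
            continue
        members = frozenset(raw)
        if len(members) < len(raw):
            result.log.append(f"complex {row.complex_id}: duplicate member ids collapsed")
        group = (row.family_group or None) if has_family else None
        parsed.append(ProteinComplex(row.complex_id, members, group))

    by_members: dict[frozenset[str], list[ProteinComplex]] = {}
    for cx in parsed:
        by_members.setdefault(cx.members, []).append(cx)
    for group in by_members.values():
        group.sort(key=lambda c: c.complex_id)
        if len(group) > 1:
            result.log.append(
                f"merged complexes {[c.complex_id for c in group[1:]]} into {group[0].complex_id}"
                " (identical member sets)"
            )
    result.complexes = sorted((g[0] for g in by_members.values()), key=lambda c: c.complex_id)
    return result


def complex_total_all_types(cx: ProteinComplex, dataset: PTMDataset) -> int:
    """Total modification records over members, all four types summed."""
    return sum(dataset[m].n_sites for m in cx.members if m in dataset)


def filter_and_collapse(
    complexes: list[ProteinComplex], dataset: PTMDataset, min_members: int = 3
) -> ComplexParseResult:
    """Drop small complexes and collapse family-expanded variants.

    Complexes with fewer than ``min_members`` unique subunits are removed.
    Within each family group only the variant with the largest total PTM count
    (all types summed) is retained; ties break to the smallest complex_id.
    """
    result = ComplexParseResult()
    kept = []
    for cx in complexes:
        if cx.size < min_members:
            result.log.append(f"drop complex {cx.complex_id}: only {cx.size} unique subunits")
        else:
            kept.append(cx)

    by_family: dict[str, list[ProteinComplex]] = {}
    for cx in kept:
        if cx.family_group is None:
            result.complexes.append(cx)
        else:
            by_family.setdefault(cx.family_group, []).append(cx)
    for fam in sorted(by_family):
        group = sorted(by_family[fam], key=lambda c: (-complex_total_all_types(c, dataset), c.complex_id))
        result.complexes.append(group[0])
        if len(group) > 1:
            result.log.append(
                f"family {fam}: kept {group[0].complex_id} "
                f"({complex_total_all_types(group[0], dataset)} total PTMs), dropped {[c.complex_id for c in group[1:]]}"
            )
    result.complexes.sort(key=lambda c: c.complex_id)
    return result


def member_counts(cx: ProteinComplex, dataset: PTMDataset, ptm_type: str) -> list[int]:
    """Per-member record counts of one type; members absent from the dataset count 0."""
    counts = []
    for m in sorted(cx.members):
        if m in dataset:
            counts.append(sum(1 for s in dataset[m].sites if s.ptm_type == ptm_type))
        else:
            counts.append(0)
    return counts


def complex_ptm_stats(cx: ProteinComplex, dataset: PTMDataset, ptm_type: str) -> ComplexStats:
    counts = member_counts(cx, dataset, ptm_type)
    return ComplexStats(cx.complex_id, ptm_type, sum(counts), float(_median(counts)), cx.size)


def stats_table(complexes: list[ProteinComplex], dataset: PTMDataset) -> pd.DataFrame:
    """Per-complex, per-type (total, median, n_members) table."""
    rows = []
    for cx in complexes:
        for t in PTM_TYPES:
            st = complex_ptm_stats(cx, dataset, t)
            rows.append((st.complex_id, st.ptm_type, st.total, st.median, st.n_members))
    return pd.DataFrame(rows, columns=["complex_id", "ptm_type", "total", "median", "n_members"])
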