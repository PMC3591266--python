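"""Site-level PTM data: parsing, validation and collation onto representative proteins.

The unit of analysis throughout the package is a *modification record*: a
unique (protein, 1-based position, PTM type) triple. Four modification types
are tracked -- lysine acetylation (``Ac``), serine/threonine phosphorylation
(``pST``), tyrosine phosphorylation (``pY``) and lysine ubiquitination
(``Ub``). A single lysine may carry both an acetylation and a ubiquitination
record, so per-window modification density can exceed the density of
modifiable residues.

Input is a tab-delimited site table anchored to protein sequences via
13-residue flanking windows (the modified residue at the centre), plus a
FASTA file of the sequences themselves. Collation merges identical sequences
published under distinct identifiers and keeps, per gene, the most highly
modified isoform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

#: Canonical PTM type order used for all per-type vectors and table columns.
PTM_TYPES: tuple[str, ...] = ("Ac", "pST", "pY", "Ub")

#: Residues each modification type may occupy.
COMPATIBLE: dict[str, frozenset[str]] = {
    "Ac": frozenset("K"),
    "Ub": frozenset("K"),
    "pY": frozenset("Y"),
    "pST": frozenset("ST"),
}

#: Padding character for flanks of sites within 6 residues of a terminus.
FLANK_PAD = "_"

SITE_TABLE_COLUMNS = ("protein_id", "gene_id", "position", "residue", "ptm_type", "flank13")


@dataclass(frozen=True, order=True)
class PTMSite:
    """One modification record anchored to a protein sequence."""

    protein_id: str
    gene_id: str
    position: int  # 1-based
    residue: str
    ptm_type: str
    flank13: str


@dataclass
class Protein:
    """A protein sequence together with its modification records."""

    protein_id: str
    gene_id: str
    sequence: str
    sites: list[PTMSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def counts_by_type(self) -> dict[str, int]:
        counts = {t: 0 for t in PTM_TYPES}
        for s in self.sites:
            counts[s.ptm_type] += 1
        return counts

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def multiplicity(self) -> int:
        """Number of distinct PTM types present (0-4)."""
        return len({s.ptm_type for s in self.sites})


@dataclass
class PTMDataset:
    """Proteins keyed by identifier plus a provenance log of collation decisions."""

    proteins: dict[str, Protein] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.proteins

    def __getitem__(self, protein_id: str) -> Protein:
        return self.proteins[protein_id]

    def __iter__(self) -> Iterator[Protein]:
        for pid in sorted(self.proteins):
            yield self.proteins[pid]

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def total_sites(self) -> int:
        return sum(p.n_sites for p in self.proteins.values())

    def counts_by_type(self) -> dict[str, int]:
        counts = {t: 0 for t in PTM_TYPES}
        for p in self.proteins.values():
            for s in p.sites:
                counts[s.ptm_type] += 1
        return counts

    def site_counts(self, ptm_type: str) -> dict[str, int]:
        """Per-protein record count for one type (zero-site proteins included)."""
        return {pid: sum(1 for s in p.sites if s.ptm_type == ptm_type) for pid, p in self.proteins.items()}


def flank13(sequence: str, position: int) -> str:
    """13-residue window centred on ``position`` (1-based), terminus-padded with '_'."""
    i = position - 1
    left = sequence[max(0, i - 6) : i].rjust(6, FLANK_PAD)
    right = sequence[i + 1 : i + 7].ljust(6, FLANK_PAD)
    return left + sequence[i] + right


def validate_site(sequence: str, position: int, residue: str, ptm_type: str, flank: str) -> str | None:
    """Return a rejection reason, or None if the record is consistent with the sequence."""
    if ptm_type not in COMPATIBLE:
        return f"unknown ptm_type {ptm_type!r}"
    if residue not in COMPATIBLE[ptm_type]:
        return f"{ptm_type} not permitted on residue {residue!r}"
    if not 1 <= position <= len(sequence):
        return f"position {position} outside sequence of length {len(sequence)}"
    if sequence[position - 1] != residue:
        return f"sequence has {sequence[position - 1]!r} at position {position}, record claims {residue!r}"
    if len(flank) != 13:
        return f"flank13 has length {len(flank)}"
    if flank[6] != residue:
        return "flank13 centre does not match the modified residue"
    if flank != flank13(sequence, position):
        return "flank13 disagrees with the sequence context"
    return None


def parse_site_table(path: str, fasta_path: str) -> PTMDataset:
    """Read a tab-delimited site table plus FASTA and build a validated dataset.

    Every FASTA record becomes a protein (so unmodified proteins are first-class
    members of the dataset); a site row naming a protein absent from the FASTA is
    a hard error. Rows violating residue compatibility, position bounds or the
    flank cross-check are rejected individually, with the reason logged. At most
    one record per (position, type) is kept; exact duplicates are deduplicated
    silently, conflicting duplicates (same position and type, different flank)
    are rejected.
    """
    dataset = PTMDataset()
    for rec in SeqIO.parse(fasta_path, "fasta"):
        pid = rec.id
        if pid in dataset.proteins:
            raise ValueError(f"duplicate FASTA identifier {pid!r}")
        dataset.proteins[pid] = Protein(pid, gene_id=pid, sequence=str(rec.seq).upper())

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SITE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"site table is missing columns: {sorted(missing)}")

    seen: dict[tuple[str, int, str], PTMSite] = {}
    n_rejected = 0
    for row in table.itertuples(index=False):
        pid = row.protein_id
        if pid not in dataset.proteins:
            raise KeyError(f"protein {pid!r} in site table has no FASTA sequence")
        protein = dataset.proteins[pid]
        try:
            position = int(row.position)
        except ValueError:
            dataset.log.append(f"reject {pid} pos={row.position!r}: non-integer position")
            n_rejected += 1
            continue
        reason = validate_site(protein.sequence, position, row.residue, row.ptm_type, row.flank13)
        if reason is not None:
            dataset.log.append(f"reject {pid} pos={position} {row.ptm_type}: {reason}")
            n_rejected += 1
            continue
        site = PTMSite(pid, row.gene_id, position, row.residue, row.ptm_type, row.flank13)
        key = (pid, position, row.ptm_type)
        if key in seen:
            if seen[key] == site:
                dataset.log.append(f"dedup {pid} pos={position} {row.ptm_type}: exact duplicate row")
            else:
                dataset.log.append(f"reject {pid} pos={position} {row.ptm_type}: conflicts with earlier record")
                n_rejected += 1
            continue
        seen[key] = site
        if protein.gene_id == pid:
            protein.gene_id = row.gene_id
        elif protein.gene_id != row.gene_id:
            dataset.log.append(
                f"reject {pid} pos={position} {row.ptm_type}: gene_id {row.gene_id!r} "
                f"conflicts with {protein.gene_id!r}"
            )
            n_rejected += 1
            del seen[key]
            continue
        protein.sites.append(site)
    for p in dataset.proteins.values():
        p.sites.sort()
    dataset.log.append(f"parsed {len(seen)} sites across {len(dataset)} proteins; rejected {n_rejected} rows")
    return dataset


def _rekey_sites(protein: Protein, sites: Iterable[PTMSite]) -> list[PTMSite]:
    return sorted(
        dataclasses.replace(s, protein_id=protein.protein_id, gene_id=protein.gene_id) for s in sites
    )


def collate(dataset: PTMDataset) -> PTMDataset:
    """Collapse identical sequences and keep one representative isoform per gene.

    Two rules, applied in order:

    1. Proteins with byte-identical sequences are merged onto a single
       identifier (the lexicographically smallest), taking the union of their
       site sets deduplicated by (position, type).
    2. Within each gene, only the isoform carrying the most modification
       records is retained; ties break to the smallest identifier.

    The operation is idempotent and never increases the total record count.
    """
    out = PTMDataset(log=list(dataset.log))

    by_seq: dict[str, list[Protein]] = {}
    for p in dataset:
        by_seq.setdefault(p.sequence, []).append(p)

    merged: list[Protein] = []
    for seq in sorted(by_seq):
        group = sorted(by_seq[seq], key=lambda p: p.protein_id)
        rep = group[0]
        union: dict[tuple[int, str], PTMSite] = {}
        for p in group:
            for s in p.sites:
                union.setdefault((s.position, s.ptm_type), s)
        new = Protein(rep.protein_id, rep.gene_id, seq)
        new.sites = _rekey_sites(new, union.values())
        if len(group) > 1:
            dropped = [p.protein_id for p in group[1:]]
            out.log.append(f"merged identical sequences {dropped} onto {rep.protein_id}")
        merged.append(new)

    by_gene: dict[str, list[Protein]] = {}
    for p in merged:
        by_gene.setdefault(p.gene_id, []).append(p)
    for gene in sorted(by_gene):
        group = sorted(by_gene[gene], key=lambda p: (-p.n_sites, p.protein_id))
        rep = group[0]
        out.proteins[rep.protein_id] = rep
        if len(group) > 1:
            dropped = [p.protein_id for p in group[1:]]
            out.log.append(f"gene {gene}: kept most-modified isoform {rep.protein_id} ({rep.n_sites} sites), dropped {dropped}")
    out.log.append(f"collated: {out.total_sites} sites across {len(out)} proteins")
    return out


def protein_ptm_profile(protein: Protein) -> tuple[dict[str, int], int]:
    """Per-type record counts and the number of distinct types present."""
    counts = protein.counts_by_type()
    return counts, sum(1 for v in counts.values() if v > 0)


def write_site_table(dataset: PTMDataset, path: str) -> None:
    """Write all site records back out in the input dialect."""
    rows = [
        (s.protein_id, s.gene_id, s.position, s.residue, s.ptm_type, s.flank13)
        for p in dataset
        for s in p.sites
    ]
    pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)
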