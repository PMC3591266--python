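"""Tiled-window cross-classification: PTM density vs domains, disorder and mutations.

Proteins are tiled with consecutive non-overlapping 20-residue windows and
each window is classified independently along four axes: modification
density (high > 0.3, medium > 0.05, low > 0, unmodified), maximum overlap
with an annotated domain (Int 20, Lg 11-19, Sm 1-10, Ext 0 residues),
disorder content from a precomputed binary per-residue track (High 20,
Med 11-19, Low 1-10, none 0 disordered residues) and cancer-mutation burden
(a window is *mutated* when it holds at least kappa records, default 2).
The aggregated fractions reproduce the domain-vs-density mutation contrast:
mutation frequency inside domains versus in dense modification windows
outside any domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ptm_dataset import PTMDataset, Protein
from .ptmi import ScanConfig, Window, _window_at

DOMAIN_CLASSES = ("Int", "Lg", "Sm", "Ext")
DISORDER_CLASSES = ("High", "Med", "Low", "none")
DENSITY_BINS = ("high", "medium", "low", "unmodified")


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    name: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str


def read_domains(path: str) -> list[DomainAnnotation]:
    """Domain table: protein_id, name, start, end (tab-delimited, 1-based inclusive)."""
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "name": str})
    return [
        DomainAnnotation(r.protein_id, r.name, int(r.start), int(r.end))
        for r in table.itertuples(index=False)
    ]


def read_disorder(path: str) -> dict[str, str]:
    """Disorder tracks: protein_id <TAB> binary string ('1' = disordered)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {r.protein_id: r.track for r in table.itertuples(index=False)}


def read_mutations(path: str, dataset: PTMDataset) -> tuple[list[MutationRecord], list[str]]:
    """Mutation table filtered to records whose annotated residue matches the sequence.

    Returns the retained records and a log of dropped rows (position out of
    bounds or reference residue mismatch), mirroring the position-consistency
    filter applied to the cancer mutation data.
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ref_aa": str, "alt_aa": str})
    kept: list[MutationRecord] = []
    log: list[str] = []
    for r in table.itertuples(index=False):
        pos = int(r.position)
        if r.protein_id not in dataset:
            log.append(f"drop mutation {r.protein_id}:{pos}: unknown protein")
            continue
        seq = dataset[r.protein_id].sequence
        if not 1 <= pos <= len(seq):
            log.append(f"drop mutation {r.protein_id}:{pos}: position out of bounds")
            continue
        if seq[pos - 1] != r.ref_aa:
            log.append(f"drop mutation {r.protein_id}:{pos}: sequence has {seq[pos - 1]}, record claims {r.ref_aa}")
            continue
        kept.append(MutationRecord(r.protein_id, pos, r.ref_aa, r.alt_aa))
    return kept, log


def tile_windows(protein: Protein, width: int = 20) -> list[Window]:
    """Consecutive non-overlapping windows at starts 1, width+1, ...

    Trailing residues that do not fill a whole window are discarded.
    """
    if len(protein) < width:
        return []
    starts = range(1, len(protein) - width + 2, width)
    return [_window_at(protein, s, width) for s in starts]


def classify_domain_overlap(window: Window, domains: list[DomainAnnotation], union: bool = False) -> str:
    """Domain-overlap class from the maximum single-domain overlap in residues.

    With ``union=True`` the overlap is counted over the union of all domain
    spans instead (alternative convention, off by default).
    """
    relevant = [d for d in domains if d.protein_id == window.protein_id]
    if union:
        covered = set()
        for d in relevant:
            covered.update(range(max(d.start, window.start), min(d.end, window.end) + 1))
        overlap = len(covered)
    else:
        overlap = 0
        for d in relevant:
            o = min(d.end, window.end) - max(d.start, window.start) + 1
            overlap = max(overlap, o)
    if overlap >= window.width:
        return "Int"
    if overlap >= 11:
        return "Lg"
    if overlap >= 1:
        return "Sm"
    return "Ext"


def classify_disorder(window: Window, track: str) -> str:
    """Disorder class from the count of disordered residues in the window."""
    span = track[window.start - 1 : window.end]
    if len(span) != window.width:
        raise ValueError(
            f"disorder track for {window.protein_id} does not cover window {window.start}-{window.end}"
        )
    n = span.count("1")
    if n >= window.width:
        return "High"
    if n >= 11:
        return "Med"
    if n >= 1:
        return "Low"
    return "none"


def classify_density_bin(window: Window, config: ScanConfig = ScanConfig()) -> str:
    """Density class: high > theta, medium > lower bound, low > 0, else unmodified.

    Boundary values go down: density exactly 0.05 is low, exactly 0.3 medium.
    """
    d = window.ptm_density
    if d > config.theta:
        return "high"
    if d > config.medium:
        return "medium"
    if d > 0:
        return "low"
    return "unmodified"


def mutations_in_window(window: Window, mutations: list[MutationRecord]) -> int:
    return sum(
        1 for m in mutations if m.protein_id == window.protein_id and window.start <= m.position <= window.end
    )


def mutated_window_flag(window: Window, mutations: list[MutationRecord], kappa: int = 2) -> bool:
    """True iff the window carries at least kappa mutation records."""
    return mutations_in_window(window, mutations) >= kappa


def window_classification_table(
    dataset: PTMDataset,
    domains: list[DomainAnnotation],
    disorder: dict[str, str] | None,
    mutations: list[MutationRecord],
    config: ScanConfig = ScanConfig(),
    kappa: int = 2,
) -> pd.DataFrame:
    """One row per tiled window with all four classifications."""
    dom_by_pid: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        dom_by_pid.setdefault(d.protein_id, []).append(d)
    mut_by_pid: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        mut_by_pid.setdefault(m.protein_id, []).append(m)

    rows = []
    for p in dataset:
        for w in tile_windows(p, config.width):
            n_mut = mutations_in_window(w, mut_by_pid.get(p.protein_id, []))
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "start": w.start,
                    "end": w.end,
                    "n_mods": w.n_mods,
                    "density_bin": classify_density_bin(w, config),
                    "domain_class": classify_domain_overlap(w, dom_by_pid.get(p.protein_id, [])),
                    "disorder_class": (
                        classify_disorder(w, disorder[p.protein_id]) if disorder is not None else None
                    ),
                    "n_mutations": n_mut,
                    "mutated": n_mut >= kappa,
                }
            )
    return pd.DataFrame(rows)


def mutated_fraction_table(
    dataset: PTMDataset,
    domains: list[DomainAnnotation],
    mutations: list[MutationRecord],
    config: ScanConfig = ScanConfig(),
    kappa: int = 2,
    restrict_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Fraction of mutated windows per domain class, and per density bin within Ext.

    Rows: the four domain-overlap classes, then the four density bins restricted
    to domain-external (Ext) windows. ``fraction`` is mutated/total windows in
    the category (NaN for an empty category). ``restrict_ids`` optionally limits
    the analysis to a tumor-suppressor/oncogene identifier list.
    """
    table = window_classification_table(dataset, domains, None, mutations, config, kappa)
    if restrict_ids is not None:
        table = table[table.protein_id.isin(restrict_ids)]
    rows = []
    for cls in DOMAIN_CLASSES:
        sub = table[table.domain_class == cls]
        rows.append(("domain", cls, len(sub), int(sub.mutated.sum())))
    ext = table[table.domain_class == "Ext"]
    for b in DENSITY_BINS:
        sub = ext[ext.density_bin == b]
        rows.append(("ext_density", b, len(sub), int(sub.mutated.sum())))
    out = pd.DataFrame(rows, columns=["axis", "category", "n_windows", "n_mutated"])
    out["fraction"] = out.n_mutated / out.n_windows
    return out
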