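"""PTM integration (PTMi) spots: sliding-window density scanning and nulls.

A 20-residue window slid at a 10-residue step across each protein measures
local modification density (records per residue; a lysine carrying both Ac
and Ub contributes two records, so density can exceed the modifiable-residue
fraction). Non-overlapping local density peaks summarise the landscape;
windows above the high-density cutoff (>0.3, i.e. at least 7 records per 20
residues and hence 2^7 = 128 occupancy states for the minimal single-type
spot) are merged into PTMi spots, classified *single* or *multi* by the
number of distinct types present. A within-protein permutation null that
shuffles only the type labels over the modified positions -- leaving the
type-blind density profile untouched -- tests whether multi-type dense
windows occur more or less often than label placement alone predicts.

Two sequence-motif annotators support the downstream biology: the tripartite
PY nuclear-localisation-signal core ([R/H/K]-X(2-5)-P-Y) and the
hyperphospho-degron rule (>=4 pS/T in a spot, at least one proline-directed,
plus >=1 ubiquitination site), the Sic1-style phosphorylation-licensed
degradation switch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .ptm_dataset import COMPATIBLE, PTM_TYPES, PTMDataset, Protein, PTMSite

STYK = frozenset("STYK")

#: Core tripartite PY-NLS pattern; overlapping matches are enumerated lazily.
PY_NLS_PATTERN = re.compile(r"(?=([RHK].{2,5}PY))")


@dataclass(frozen=True)
class ScanConfig:
    """Window scanning parameters.

    width
        window span in residues (20).
    step
        start-to-start offset for the overlapping scan (10); tiled scanning
        uses ``step == width``.
    theta
        high-density cutoff: a window is *high* when records/width > theta (0.3).
    medium
        lower bound of the medium density class (>0.05 and <= theta).
    """

    width: int = 20
    step: int = 10
    theta: float = 0.3
    medium: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.step <= self.width:
            raise ValueError("require 1 <= step <= width")
        if not 0 < self.theta < 2:
            raise ValueError("require 0 < theta < 2")


@dataclass(frozen=True)
class Window:
    protein_id: str
    start: int  # 1-based inclusive
    width: int
    n_mods: int
    type_counts: tuple[int, int, int, int]  # aligned with PTM_TYPES
    styk_density: float

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    @property
    def ptm_density(self) -> float:
        return self.n_mods / self.width

    @property
    def n_types(self) -> int:
        return sum(1 for c in self.type_counts if c > 0)

    def overlaps(self, other: "Window") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class PTMiSpot:
    protein_id: str
    start: int
    end: int  # inclusive
    n_mods: int
    types: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        return self.n_mods / self.length

    @property
    def classification(self) -> str:
        return "single" if len(self.types) == 1 else "multi"


def _window_at(protein: Protein, start: int, width: int) -> Window:
    end = start + width - 1
    counts = [0, 0, 0, 0]
    for s in protein.sites:
        if start <= s.position <= end:
            counts[PTM_TYPES.index(s.ptm_type)] += 1
    span = protein.sequence[start - 1 : end]
    styk = sum(1 for aa in span if aa in STYK) / width
    return Window(protein.protein_id, start, width, sum(counts), tuple(counts), styk)


def scan_windows(protein: Protein, config: ScanConfig = ScanConfig()) -> list[Window]:
    """Overlapping scan: windows at starts 1, 1+step, ... while they fit.

    A protein shorter than the window width yields no windows; a trailing
    region shorter than the width after the last valid start is not scanned.
    """
    if len(protein) < config.width:
        return []
    starts = range(1, len(protein) - config.width + 2, config.step)
    return [_window_at(protein, s, config.width) for s in starts]


def local_peaks(windows: list[Window]) -> list[Window]:
    """Greedy non-overlapping local density maxima of an overlapping scan.

    A candidate is a modified window (>=1 record) whose density is >= that of
    both span-overlapping neighbours in scan order (edge windows compare only
    the neighbour that exists). Candidates are then admitted in order of
    descending density (ties leftmost-first), discarding any that overlap an
    already-admitted peak.
    """
    candidates = []
    for i, w in enumerate(windows):
        if w.n_mods < 1:
            continue
        d = w.ptm_density
        if i > 0 and windows[i - 1].overlaps(w) and windows[i - 1].ptm_density > d:
            continue
        if i + 1 < len(windows) and windows[i + 1].overlaps(w) and windows[i + 1].ptm_density > d:
            continue
        candidates.append(w)
    chosen: list[Window] = []
    for w in sorted(candidates, key=lambda w: (-w.ptm_density, w.start)):
        if not any(w.overlaps(c) for c in chosen):
            chosen.append(w)
    return sorted(chosen, key=lambda w: w.start)


def min_sites_exceeding(width: int, theta: float) -> int:
    """Smallest record count k with k/width strictly above the density cutoff."""
    if width < 1:
        raise ValueError("width must be >= 1")
    for k in range(width * 2 + 1):
        if k / width > theta:
            return k
    raise ValueError("theta out of range")


def modification_states(k: int) -> int:
    """Number of binary occupancy states of k modifiable sites."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2**k


def call_spots(protein: Protein, config: ScanConfig = ScanConfig()) -> list[PTMiSpot]:
    """Merge high-density scan windows into disjoint PTMi spots.

    Windows with density > theta whose spans overlap or abut are unioned; the
    spot density is recomputed over the merged span. Classification is
    *single* when one modification type is present in the span, *multi*
    otherwise. No upper length cap is applied.
    """
    dense = [w for w in scan_windows(protein, config) if w.ptm_density > config.theta]
    if not dense:
        return []
    spans: list[list[int]] = []
    for w in dense:
        if spans and w.start <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], w.end)
        else:
            spans.append([w.start, w.end])
    spots = []
    for start, end in spans:
        in_span = [s for s in protein.sites if start <= s.position <= end]
        types = tuple(t for t in PTM_TYPES if any(s.ptm_type == t for s in in_span))
        spots.append(PTMiSpot(protein.protein_id, start, end, len(in_span), types))
    return spots


def permute_types_within_protein(
    protein: Protein, seed: int | np.random.Generator, mode: str = "literal"
) -> Protein:
    """Shuffle the multiset of type labels over the modified positions.

    The modified positions (including doubly-occupied ones) are fixed; only
    which label sits where is permuted, so the type-blind density profile and
    the per-type global counts are exactly conserved. ``mode="literal"``
    permutes all labels jointly (a label can land on a residue it could not
    chemically occupy -- the null deliberately ignores residue identity);
    ``mode="compatible"`` permutes labels only among positions whose residue
    class could host them (Ac/Ub among K slots, pST among S/T, pY among Y).
    Proteins with fewer than two records are returned unchanged.
    """
    if len(protein.sites) < 2:
        return protein
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = sorted(protein.sites)
    labels = [s.ptm_type for s in sites]
    if mode == "literal":
        order = rng.permutation(len(labels))
        new_labels = [labels[i] for i in order]
    elif mode == "compatible":
        new_labels = list(labels)
        classes = {"K": {"Ac", "Ub"}, "Y": {"pY"}, "ST": {"pST"}}
        for members in classes.values():
            idx = [i for i, lab in enumerate(labels) if lab in members]
            order = rng.permutation(len(idx))
            for slot, j in zip(idx, order):
                new_labels[slot] = labels[idx[j]]
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    new_sites = [replace(s, ptm_type=lab) for s, lab in zip(sites, new_labels)]
    return Protein(protein.protein_id, protein.gene_id, protein.sequence, new_sites)


def _high_density_type_counts(protein: Protein, config: ScanConfig) -> tuple[int, int]:
    """(single-type, multi-type) counts of high-density windows in one protein."""
    single = multi = 0
    for w in scan_windows(protein, config):
        if w.ptm_density > config.theta:
            if w.n_types >= 2:
                multi += 1
            else:
                single += 1
    return single, multi


def multi_ptm_high_density_counts(
    dataset: PTMDataset,
    config: ScanConfig = ScanConfig(),
    R: int = 100,
    seed: int = 0,
    mode: str = "literal",
) -> dict:
    """Observed vs within-protein-permutation counts of dense windows by type mix.

    Counts high-density windows across the whole dataset, split into
    single-type and multi-type, then repeats the count on R datasets in which
    each protein's type labels were independently shuffled. Returns the
    observed pair and the (R,)-arrays of null counts.
    """
    obs_single = obs_multi = 0
    for p in dataset:
        s, m = _high_density_type_counts(p, config)
        obs_single += s
        obs_multi += m
    rng = np.random.default_rng(seed)
    null_single = np.zeros(R, dtype=np.int64)
    null_multi = np.zeros(R, dtype=np.int64)
    for r in range(R):
        for p in dataset:
            s, m = _high_density_type_counts(permute_types_within_protein(p, rng, mode=mode), config)
            null_single[r] += s
            null_multi[r] += m
    return {
        "observed_single": obs_single,
        "observed_multi": obs_multi,
        "null_single": null_single,
        "null_multi": null_multi,
    }


@dataclass(frozen=True)
class PYNLSMatch:
    protein_id: str
    start: int  # 1-based, the basic residue
    end: int  # the motif tyrosine
    motif: str
    upstream10: str  # ten residues preceding the match, for manual inspection
    sites_in_span: tuple[PTMSite, ...]
    py_phosphorylated: bool  # pY record on the motif tyrosine itself


def find_py_nls(protein: Protein) -> list[PYNLSMatch]:
    """All (possibly overlapping) matches of the tripartite PY-NLS core.

    Each match carries the modification records inside its span and a flag for
    phosphorylation of the strictly conserved motif tyrosine. The upstream
    hydrophobic/basic stretch the full consensus requires is not scored; the
    preceding ten residues are reported for inspection instead.
    """
    matches = []
    for m in PY_NLS_PATTERN.finditer(protein.sequence):
        motif = m.group(1)
        start = m.start() + 1
        end = start + len(motif) - 1
        in_span = tuple(s for s in protein.sites if start <= s.position <= end)
        flagged = any(s.position == end and s.ptm_type == "pY" for s in in_span)
        upstream = protein.sequence[max(0, m.start() - 10) : m.start()]
        matches.append(PYNLSMatch(protein.protein_id, start, end, motif, upstream, in_span, flagged))
    return matches


def find_hyperphospho_degrons(spots: list[PTMiSpot], dataset: PTMDataset) -> list[PTMiSpot]:
    """Spots matching the phosphorylation-licensed degradation rule.

    Retained iff the span holds >=4 pS/T records, at least one of them
    proline-directed (the phosphosite immediately followed by P), and >=1
    ubiquitination record.
    """
    out = []
    for spot in spots:
        protein = dataset[spot.protein_id]
        pst = [s for s in protein.sites if s.ptm_type == "pST" and spot.start <= s.position <= spot.end]
        if len(pst) < 4:
            continue
        proline_directed = any(
            s.position < len(protein) and protein.sequence[s.position] == "P" for s in pst
        )
        if not proline_directed:
            continue
        has_ub = any(
            s.ptm_type == "Ub" and spot.start <= s.position <= spot.end for s in protein.sites
        )
        if has_ub:
            out.append(spot)
    return out


def dataset_spots(dataset: PTMDataset, config: ScanConfig = ScanConfig()) -> list[PTMiSpot]:
    """All PTMi spots across a dataset, ordered by protein and start."""
    spots: list[PTMiSpot] = []
    for p in dataset:
        spots.extend(call_spots(p, config))
    return spots


def dataset_peaks(dataset: PTMDataset, config: ScanConfig = ScanConfig()) -> list[Window]:
    """All non-overlapping local density peaks across a dataset."""
    peaks: list[Window] = []
    for p in dataset:
        peaks.extend(local_peaks(scan_windows(p, config)))
    return peaks
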