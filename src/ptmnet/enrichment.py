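"""Covariate-controlled annotation-permutation null and enriched-complex selection.

Modification counts correlate weakly with both protein length and how often a
protein appears across complexes, so a naive shuffle of modification bundles
would confound enrichment with size. The null model therefore bins
complex-member proteins into a 4x4 grid of complex-frequency quartile x
sequence-length quartile and permutes whole per-protein modification bundles
only within a bin, keeping all records of one protein linked. Pooling the
(total, median) coordinates of every complex over R such randomised datasets
yields a null cloud per PTM type; a complex is called enriched when the
fraction q of null points dominating its observed pair in *both* coordinates
falls below 1 - c for the per-type confidence c (0.99 for Ac, pY and Ub,
0.95 for pS/T by default).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .complex_dataset import ComplexStats, ProteinComplex, complex_ptm_stats
from .ptm_dataset import PTM_TYPES, PTMDataset, Protein, PTMSite

DEFAULT_CONFIDENCE: dict[str, float] = {"Ac": 0.99, "pST": 0.95, "pY": 0.99, "Ub": 0.99}


@dataclass
class BinScheme:
    """Partition of complex-member proteins for annotation permutation."""

    bins: dict[str, int]  # protein_id -> bin index
    n_bins: int
    freq_boundaries: list[float]
    length_boundaries: list[float]
    log: list[str] = field(default_factory=list)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid in sorted(self.bins):
            out.setdefault(self.bins[pid], []).append(pid)
        return out


@dataclass
class NullCloud:
    """Pooled (total, median) pairs from R permutation replicates, one array per type."""

    pairs: dict[str, np.ndarray]  # ptm_type -> (R * n_complexes, 2)
    R: int
    seed: int


@dataclass
class EnrichmentResult:
    ptm_type: str
    confidence: float
    table: pd.DataFrame  # complex_id, total, median, q, selected
    selected: set[str]


def _quartile_index(value: float, boundaries: list[float]) -> int:
    # values equal to a boundary fall into the lower quartile
    return bisect_left(boundaries, value)


def complex_frequency(complexes: list[ProteinComplex]) -> dict[str, int]:
    """Number of complexes each protein appears in."""
    freq: dict[str, int] = {}
    for cx in complexes:
        for m in cx.members:
            freq[m] = freq.get(m, 0) + 1
    return freq


def assign_bins(dataset: PTMDataset, complexes: list[ProteinComplex]) -> BinScheme:
    """Bin complex-member proteins by complex-frequency quartile x length quartile.

    Only members with a sequence in the dataset are binned (unknown members carry
    no modifications to shuffle). A covariate that is constant across proteins
    collapses its axis, with the fallback logged; with both axes degenerate a
    single bin remains.
    """
    freq = complex_frequency(complexes)
    pids = sorted(pid for pid in freq if pid in dataset)
    if len(pids) < 16:
        raise ValueError(f"need at least 16 distinct complex-member proteins, got {len(pids)}")

    freqs = np.array([freq[p] for p in pids], dtype=float)
    lengths = np.array([len(dataset[p]) for p in pids], dtype=float)
    log: list[str] = []

    def axis_boundaries(values: np.ndarray, name: str) -> list[float]:
        if values.min() == values.max():
            log.append(f"{name} covariate is constant; axis collapsed to a single stratum")
            return []
        return [float(b) for b in np.quantile(values, [0.25, 0.5, 0.75])]

    fb = axis_boundaries(freqs, "complex-frequency")
    lb = axis_boundaries(lengths, "length")
    n_f = len(fb) + 1 if fb else 1
    n_l = len(lb) + 1 if lb else 1

    bins: dict[str, int] = {}
    for p, f, L in zip(pids, freqs, lengths):
        fi = _quartile_index(f, fb) if fb else 0
        li = _quartile_index(L, lb) if lb else 0
        bins[p] = fi * n_l + li
    sizes = pd.Series(list(bins.values())).value_counts().sort_index()
    log.append(f"{n_f * n_l} bins; sizes {sizes.to_dict()}")
    return BinScheme(bins, n_f * n_l, fb, lb, log)


def _bundle_mapping(scheme: BinScheme, rng: np.random.Generator) -> dict[str, str]:
    """Draw one within-bin permutation: source protein -> protein receiving its bundle."""
    mapping: dict[str, str] = {}
    for _, pids in sorted(scheme.members().items()):
        perm = rng.permutation(len(pids))
        for i, j in enumerate(perm):
            mapping[pids[i]] = pids[j]
    return mapping


def permute_annotations(dataset: PTMDataset, scheme: BinScheme, seed: int | np.random.Generator) -> PTMDataset:
    """Permute whole per-protein modification bundles within bins.

    The bundle of every binned protein moves as a unit to another protein of
    the same bin; per-bin bundle multisets and global per-type totals are
    conserved exactly. Site records keep their original positions and flanks
    (the permuted dataset is a counting null, not a sequence-consistent one);
    proteins outside the scheme are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mapping = _bundle_mapping(scheme, rng)
    out = PTMDataset(log=[f"annotation permutation over {scheme.n_bins} bins"])
    for pid, protein in dataset.proteins.items():
        out.proteins[pid] = Protein(pid, protein.gene_id, protein.sequence, [])
    for src, dst in mapping.items():
        target = out.proteins[dst]
        target.sites = [
            PTMSite(dst, target.gene_id, s.position, s.residue, s.ptm_type, s.flank13)
            for s in dataset[src].sites
        ]
    for pid, protein in dataset.proteins.items():
        if pid not in mapping:
            out.proteins[pid].sites = list(protein.sites)
    return out


def build_null(
    dataset: PTMDataset,
    complexes: list[ProteinComplex],
    scheme: BinScheme,
    R: int = 100,
    seed: int = 0,
) -> NullCloud:
    """Pool (total, median) pairs over R annotation-permutation replicates.

    Uses a per-protein count-matrix fast path: a bundle permutation only moves
    per-type counts between identifiers, so complex statistics can be recomputed
    without rebuilding site records.
    """
    pids = sorted(scheme.bins)
    index = {p: i for i, p in enumerate(pids)}
    counts = np.zeros((len(pids), len(PTM_TYPES)), dtype=np.int64)
    for t_i, t in enumerate(PTM_TYPES):
        per_protein = dataset.site_counts(t)
        for p, i in index.items():
            counts[i, t_i] = per_protein.get(p, 0)

    member_idx = [np.array([index[m] for m in sorted(cx.members) if m in index], dtype=np.intp) for cx in complexes]
    member_n = [cx.size for cx in complexes]

    rng = np.random.default_rng(seed)
    pools: dict[str, list[np.ndarray]] = {t: [] for t in PTM_TYPES}
    for _ in range(R):
        mapping = _bundle_mapping(scheme, rng)
        perm_counts = np.zeros_like(counts)
        for src, dst in mapping.items():
            perm_counts[index[dst]] = counts[index[src]]
        for t_i, t in enumerate(PTM_TYPES):
            pairs = np.empty((len(complexes), 2))
            for c_i, (idx, n) in enumerate(zip(member_idx, member_n)):
                vec = np.zeros(n, dtype=np.int64)
                vec[: len(idx)] = perm_counts[idx, t_i]
                pairs[c_i, 0] = vec.sum()
                pairs[c_i, 1] = np.median(vec)
            pools[t].append(pairs)
    return NullCloud({t: np.vstack(pools[t]) for t in PTM_TYPES}, R=R, seed=seed)


def select_enriched(stats: list[ComplexStats], null: NullCloud, confidence: float) -> EnrichmentResult:
    """Joint empirical exceedance against the null cloud of one PTM type.

    For each complex, q is the fraction of null (total, median) pairs at least
    as large as the observed pair in both coordinates; the complex is selected
    when q < 1 - confidence. The rule is monotone in both coordinates, so the
    selection at a higher confidence is always a subset of that at a lower one.
    """
    if not stats:
        raise ValueError("no complex statistics supplied")
    ptm_type = stats[0].ptm_type
    if any(s.ptm_type != ptm_type for s in stats):
        raise ValueError("mixed ptm_type in stats")
    cloud = null.pairs[ptm_type]
    if cloud.size == 0:
        raise ValueError("empty null cloud")
    rows = []
    selected: set[str] = set()
    for s in stats:
        q = float(np.mean((cloud[:, 0] >= s.total) & (cloud[:, 1] >= s.median)))
        hit = q < 1.0 - confidence
        if hit:
            selected.add(s.complex_id)
        rows.append((s.complex_id, s.total, s.median, q, hit))
    table = pd.DataFrame(rows, columns=["complex_id", "total", "median", "q", "selected"])
    return EnrichmentResult(ptm_type, confidence, table, selected)


def run_enrichment(
    dataset: PTMDataset,
    complexes: list[ProteinComplex],
    R: int = 100,
    seed: int = 0,
    confidence: dict[str, float] | None = None,
) -> tuple[dict[str, EnrichmentResult], NullCloud, BinScheme]:
    """Full selection pass: binning, null construction, per-type selection."""
    conf = dict(DEFAULT_CONFIDENCE)
    if confidence:
        conf.update(confidence)
    scheme = assign_bins(dataset, complexes)
    null = build_null(dataset, complexes, scheme, R=R, seed=seed)
    results = {}
    for t in PTM_TYPES:
        stats = [complex_ptm_stats(cx, dataset, t) for cx in complexes]
        results[t] = select_enriched(stats, null, conf[t])
    return results, null, scheme


def overlap_enriched(results: dict[str, EnrichmentResult]) -> dict:
    """Cross-type overlap of the enriched sets.

    Returns the per-complex membership table, counts for every non-empty type
    combination, the set of complexes enriched for >=3 types and the set
    enriched for both Ac and Ub.
    """
    sets = {t: results[t].selected for t in PTM_TYPES}
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {t: [cid in sets[t] for cid in universe] for t in PTM_TYPES}, index=pd.Index(universe, name="complex_id")
    )
    combo_counts: dict[tuple[str, ...], int] = {}
    for cid in universe:
        combo = tuple(t for t in PTM_TYPES if cid in sets[t])
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(PTM_TYPES, 2)
    }
    three_plus = {cid for cid in universe if sum(cid in sets[t] for t in PTM_TYPES) >= 3}
    return {
        "membership": membership,
        "combination_counts": combo_counts,
        "pairwise": pairwise,
        "three_plus": three_plus,
        "ac_ub": sets["Ac"] & sets["Ub"],
    }
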