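"""Synthetic proteome, PTM, complex and annotation generator.

Emits complete inputs with the statistical structure the analysis assumes --
per-residue background modification rates with realistic type proportions,
dense type-pure (or mixed) modification hotspots in residue-biased spans,
complexes whose designated members carry an elevated rate of one target
type, plus domain, disorder and mutation annotations with controlled rate
ratios -- together with a ground-truth manifest, so every pipeline stage can
be exercised and calibrated without any external download.

Default rates reproduce the qualitative ordering of the real collated data
(pS/T >> Ub > pY > Ac, roughly 56/24/13/7 percent of records) at an overall
background of about 0.015 records per residue. Hotspot spans are 20-60
residues, mirroring the 20-90 residue lengths of observed dense spots, and
are compositionally biased toward the compatible residues of their type so
that a 20-residue window can physically hold 7+ records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .complex_dataset import ProteinComplex
from .ptm_dataset import COMPATIBLE, PTM_TYPES, PTMDataset, Protein, PTMSite, flank13

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Per-compatible-residue background rates; proportions follow the observed
#: per-type record shares at ~0.015 records/residue overall under uniform composition.
DEFAULT_BACKGROUND_RATES: dict[str, float] = {"Ac": 0.020, "pST": 0.084, "pY": 0.040, "Ub": 0.072}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's standard study conditions."""

    n_proteins: int = 300
    length_log_mean: float = 6.0  # lognormal median ~400 residues
    length_log_sd: float = 0.35
    min_length: int = 60
    aa_freqs: dict[str, float] | None = None  # None -> uniform over the 20 amino acids

    background_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_RATES))

    hotspot_probability: float = 0.15  # per-protein probability of carrying one hotspot
    hotspot_span: tuple[int, int] = (20, 60)
    hotspot_rate: float = 0.75  # per compatible residue inside the span
    hotspot_compatible_fraction: float = 0.55  # composition bias inside the span
    hotspot_type_pure: bool = True

    n_complexes: int = 80
    complex_size: tuple[int, int] = (3, 8)
    enriched_fraction: float = 0.1
    enriched_type: str = "pST"
    enriched_multiplier: float = 5.0

    domains_per_protein: float = 1.2  # Poisson mean
    domain_length: tuple[int, int] = (50, 150)
    disorder_segments_per_protein: float = 1.0
    disorder_length: tuple[int, int] = (30, 80)
    mutation_rate_outside: float = 0.002  # per residue, outside domains and dense windows
    mutation_domain_ratio: float = 3.0
    mutation_dense_ratio: float = 3.0

    seed: int = 0


@dataclass
class SyntheticBundle:
    """In-memory outputs plus the ground-truth manifest."""

    config: SyntheticConfig
    dataset: PTMDataset
    complexes: list[ProteinComplex]
    enriched_complexes: set[str]
    hotspots: dict[str, list[tuple[int, int, str]]]  # protein_id -> [(start, end, type)]
    domains: pd.DataFrame  # protein_id, name, start, end
    disorder: dict[str, str]
    mutations: pd.DataFrame  # protein_id, position, ref_aa, alt_aa

    @property
    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "enriched_complexes": sorted(self.enriched_complexes),
            "hotspots": {p: [list(h) for h in hs] for p, hs in sorted(self.hotspots.items())},
        }


def _draw_sequence(length: int, rng: np.random.Generator, freqs: dict[str, float] | None) -> list[str]:
    if freqs is None:
        return list(rng.choice(list(AMINO_ACIDS), size=length))
    aas = sorted(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    return list(rng.choice(aas, size=length, p=p / p.sum()))


def generate_proteome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, list[tuple[int, int, str]]]]:
    """Sequences plus ground-truth hotspot spans.

    Hotspot spans are redrawn with ``hotspot_compatible_fraction`` of their
    residues taken from the compatible residues of the span's assigned type
    (all of S/T/Y/K for a mixed span), emulating the low-complexity,
    modifiable-residue-rich character of real dense regions.
    """
    proteins: dict[str, str] = {}
    hotspots: dict[str, list[tuple[int, int, str]]] = {}
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        pid = f"P{i + 1:0{width}d}"
        length = max(config.min_length, int(rng.lognormal(config.length_log_mean, config.length_log_sd)))
        seq = _draw_sequence(length, rng, config.aa_freqs)
        if rng.random() < config.hotspot_probability:
            span_len = int(rng.integers(config.hotspot_span[0], config.hotspot_span[1] + 1))
            span_len = min(span_len, length)
            start = int(rng.integers(1, length - span_len + 2))
            hs_type = str(rng.choice(PTM_TYPES))
            pool = sorted(COMPATIBLE[hs_type]) if config.hotspot_type_pure else list("STYK")
            for j in range(start - 1, start - 1 + span_len):
                if rng.random() < config.hotspot_compatible_fraction:
                    seq[j] = str(rng.choice(pool))
            hotspots[pid] = [(start, start + span_len - 1, hs_type)]
        proteins[pid] = "".join(seq)
    return proteins, hotspots


def implant_sites(
    proteins: dict[str, str],
    hotspots: dict[str, list[tuple[int, int, str]]],
    config: SyntheticConfig,
    rng: np.random.Generator,
    elevated_proteins: set[str] = frozenset(),
) -> PTMDataset:
    """Bernoulli site placement per (residue, compatible type).

    Background rates apply everywhere; inside a hotspot span the span's type
    (or every type, for a mixed span) is modified at ``hotspot_rate``; members
    of enriched complexes carry ``enriched_multiplier`` times the background
    rate of the target type across their whole sequence. Every emitted record
    is sequence-consistent by construction (residue match, exact flank).
    """
    dataset = PTMDataset()
    for pid in sorted(proteins):
        seq = proteins[pid]
        protein = Protein(pid, pid, seq)
        spans = hotspots.get(pid, [])
        for pos0, aa in enumerate(seq):
            position = pos0 + 1
            for t in PTM_TYPES:
                if aa not in COMPATIBLE[t]:
                    continue
                rate = config.background_rates[t]
                if pid in elevated_proteins and t == config.enriched_type:
                    rate = min(1.0, rate * config.enriched_multiplier)
                for start, end, hs_type in spans:
                    if start <= position <= end and (hs_type == t or not config.hotspot_type_pure):
                        rate = config.hotspot_rate
                if rng.random() < rate:
                    protein.sites.append(PTMSite(pid, pid, position, aa, t, flank13(seq, position)))
        protein.sites.sort()
        dataset.proteins[pid] = protein
    dataset.log.append(f"synthetic: {dataset.total_sites} sites across {len(dataset)} proteins")
    return dataset


def generate_complex_set(
    proteins: dict[str, str], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[ProteinComplex], set[str], set[str]]:
    """Complex memberships with a designated enriched subset.

    Returns (complexes, enriched complex ids, union of enriched-complex
    members). Enriched members are drawn from proteins not already claimed by
    another enriched complex so that the implanted signal is complex-specific.
    """
    pids = sorted(proteins)
    n_enriched = int(round(config.enriched_fraction * config.n_complexes))
    complexes: list[ProteinComplex] = []
    enriched_ids: set[str] = set()
    elevated: set[str] = set()
    width = len(str(config.n_complexes))
    for i in range(config.n_complexes):
        cid = f"C{i + 1:0{width}d}"
        size = int(rng.integers(config.complex_size[0], config.complex_size[1] + 1))
        if i < n_enriched:
            pool = [p for p in pids if p not in elevated]
            members = [pool[j] for j in rng.choice(len(pool), size=size, replace=False)]
            enriched_ids.add(cid)
            elevated.update(members)
        else:
            members = [pids[j] for j in rng.choice(len(pids), size=size, replace=False)]
        complexes.append(ProteinComplex(cid, frozenset(members)))
    return complexes, enriched_ids, elevated


def _place_segments(
    length: int, n_segments: int, seg_range: tuple[int, int], rng: np.random.Generator, max_tries: int = 50
) -> list[tuple[int, int]]:
    """Place non-overlapping (start, end) segments by rejection sampling."""
    placed: list[tuple[int, int]] = []
    for _ in range(n_segments):
        for _ in range(max_tries):
            seg_len = int(rng.integers(seg_range[0], seg_range[1] + 1))
            if seg_len > length:
                break
            start = int(rng.integers(1, length - seg_len + 2))
            end = start + seg_len - 1
            if all(end < s or start > e for s, e in placed):
                placed.append((start, end))
                break
    return sorted(placed)


def generate_annotations(
    proteins: dict[str, str],
    dataset: PTMDataset,
    config: SyntheticConfig,
    rng: np.random.Generator,
    window_width: int = 20,
    density_theta: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Domains, disorder tracks and mutations with controlled rate structure.

    Mutations fall per residue at ``mutation_rate_outside``, multiplied by
    ``mutation_domain_ratio`` inside a domain and by ``mutation_dense_ratio``
    inside a dense tiled modification window (multiplicatively when both).
    """
    domain_rows = []
    disorder: dict[str, str] = {}
    mutation_rows = []
    for pid in sorted(proteins):
        seq = proteins[pid]
        length = len(seq)

        n_dom = int(rng.poisson(config.domains_per_protein))
        doms = _place_segments(length, n_dom, config.domain_length, rng)
        for k, (s, e) in enumerate(doms):
            domain_rows.append((pid, f"{pid}_dom{k + 1}", s, e))

        n_dis = int(rng.poisson(config.disorder_segments_per_protein))
        track = np.zeros(length, dtype=np.int8)
        for s, e in _place_segments(length, n_dis, config.disorder_length, rng):
            track[s - 1 : e] = 1
        disorder[pid] = "".join("1" if v else "0" for v in track)

        in_domain = np.zeros(length, dtype=bool)
        for s, e in doms:
            in_domain[s - 1 : e] = True
        in_dense = np.zeros(length, dtype=bool)
        protein = dataset[pid]
        for start in range(1, length - window_width + 2, window_width):
            end = start + window_width - 1
            n_mods = sum(1 for st in protein.sites if start <= st.position <= end)
            if n_mods / window_width > density_theta:
                in_dense[start - 1 : end] = True
        for pos0 in range(length):
            rate = config.mutation_rate_outside
            if in_domain[pos0]:
                rate *= config.mutation_domain_ratio
            if in_dense[pos0]:
                rate *= config.mutation_dense_ratio
            if rng.random() < rate:
                ref = seq[pos0]
                alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
                mutation_rows.append((pid, pos0 + 1, ref, alt))

    domains = pd.DataFrame(domain_rows, columns=["protein_id", "name", "start", "end"])
    mutations = pd.DataFrame(mutation_rows, columns=["protein_id", "position", "ref_aa", "alt_aa"])
    return domains, disorder, mutations


def simulate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Run all generator stages from one master seed (byte-reproducible)."""
    config = config or SyntheticConfig()
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng_prot, rng_cx, rng_sites, rng_ann = (np.random.default_rng(s) for s in ss.spawn(4))

    proteins, hotspots = generate_proteome(config, rng_prot)
    complexes, enriched_ids, elevated = generate_complex_set(proteins, config, rng_cx)
    dataset = implant_sites(proteins, hotspots, config, rng_sites, elevated_proteins=elevated)
    domains, disorder, mutations = generate_annotations(proteins, dataset, config, rng_ann)
    return SyntheticBundle(config, dataset, complexes, enriched_ids, hotspots, domains, disorder, mutations)


def hotspot_protein(
    protein_id: str,
    length: int,
    span_start: int,
    span_len: int,
    n_sites: int,
    ptm_type: str,
    background_rate: float,
    rng: np.random.Generator,
) -> Protein:
    """A single protein with exactly ``n_sites`` records of one type in one span.

    The span is built with enough compatible residues to host the requested
    count; outside the span, background records of the same type fall per
    compatible residue at ``background_rate``. Used for spot-recovery
    calibration where the implanted count must be exact.
    """
    if n_sites > span_len:
        raise ValueError("cannot place more sites than span residues")
    seq = _draw_sequence(length, rng, None)
    pool = sorted(COMPATIBLE[ptm_type])
    span_idx = list(range(span_start - 1, span_start - 1 + span_len))
    comp_idx = [int(i) for i in rng.choice(span_idx, size=max(n_sites, int(span_len * 0.6)), replace=False)]
    for i in comp_idx:
        seq[i] = str(rng.choice(pool))
    sequence = "".join(seq)
    protein = Protein(protein_id, protein_id, sequence)
    for i in sorted(int(j) for j in rng.choice(comp_idx, size=n_sites, replace=False)):
        protein.sites.append(PTMSite(protein_id, protein_id, i + 1, sequence[i], ptm_type, flank13(sequence, i + 1)))
    for i, aa in enumerate(sequence):
        if i in span_idx or aa not in COMPATIBLE[ptm_type]:
            continue
        if rng.random() < background_rate:
            protein.sites.append(PTMSite(protein_id, protein_id, i + 1, aa, ptm_type, flank13(sequence, i + 1)))
    protein.sites.sort()
    return protein


# ---------------------------------------------------------------------------
# writers: emit exactly the dialects the parsing modules consume


def write_bundle(bundle: SyntheticBundle, outdir: str) -> dict[str, str]:
    """Write FASTA, site/complex/domain/disorder/mutation tables and the manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("fasta", "proteome.fasta"),
        ("sites", "sites.tsv"),
        ("complexes", "complexes.tsv"),
        ("domains", "domains.tsv"),
        ("disorder", "disorder.tsv"),
        ("mutations", "mutations.tsv"),
        ("manifest", "manifest.json"),
    ]}

    with open(paths["fasta"], "w") as fh:
        for p in bundle.dataset:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")

    site_rows = [
        (s.protein_id, s.gene_id, s.position, s.residue, s.ptm_type, s.flank13)
        for p in bundle.dataset
        for s in p.sites
    ]
    pd.DataFrame(
        site_rows, columns=["protein_id", "gene_id", "position", "residue", "ptm_type", "flank13"]
    ).to_csv(paths["sites"], sep="\t", index=False)

    cx_rows = [(cx.complex_id, ";".join(sorted(cx.members)), cx.family_group or "") for cx in bundle.complexes]
    pd.DataFrame(cx_rows, columns=["complex_id", "members", "family_group"]).to_csv(
        paths["complexes"], sep="\t", index=False
    )

    bundle.domains.to_csv(paths["domains"], sep="\t", index=False)
    pd.DataFrame(
        [(pid, track) for pid, track in sorted(bundle.disorder.items())], columns=["protein_id", "track"]
    ).to_csv(paths["disorder"], sep="\t", index=False)
    bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    return paths
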