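"""End-to-end orchestration: collation -> enrichment -> integration -> spots -> overlay.

All stage parameters live in :class:`RunConfig` with the analysis defaults
(20-residue windows at 10-residue step, density cutoff 0.3, 100 permutation
replicates, 1000 complex resamples, 99%/95% confidences, mutation cutoff 2).
Every source of randomness flows from the single ``seed``; a rerun with an
identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import complex_dataset, enrichment, integration, overlay, ptm_dataset, ptmi
from .ptm_dataset import PTM_TYPES


@dataclass
class RunConfig:
    sites: str = "sites.tsv"
    fasta: str = "proteome.fasta"
    complexes: str = "complexes.tsv"
    domains: str | None = None
    disorder: str | None = None
    mutations: str | None = None
    tumor_ids: str | None = None
    outdir: str = "ptmnet_out"

    width: int = 20
    step: int = 10
    theta: float = 0.3
    medium: float = 0.05
    confidence: dict[str, float] = field(default_factory=lambda: dict(enrichment.DEFAULT_CONFIDENCE))
    R: int = 100
    S: int = 1000
    kappa: int = 2
    permutation_mode: str = "literal"
    seed: int = 0

    run_enrichment: bool = True
    run_integration: bool = True
    run_scan: bool = True
    run_overlay: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def scan_config(self) -> ptmi.ScanConfig:
        return ptmi.ScanConfig(self.width, self.step, self.theta, self.medium)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write all tables plus a summary report.

    Returns the summary dict; raises with a stage-tagged message on any
    validation failure.
    """
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {"seed": config.seed, "config": dataclasses.asdict(config)}
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731

    try:
        dataset = ptm_dataset.parse_site_table(config.sites, config.fasta)
    except Exception as exc:
        raise RuntimeError(f"[parse] {exc}") from exc
    dataset = ptm_dataset.collate(dataset)
    ptm_dataset.write_site_table(dataset, out("collated_sites.tsv"))
    summary["dataset"] = {
        "n_proteins": len(dataset),
        "n_sites": dataset.total_sites,
        "per_type": dataset.counts_by_type(),
    }

    try:
        parsed = complex_dataset.parse_complexes(config.complexes)
        filtered = complex_dataset.filter_and_collapse(parsed.complexes, dataset)
    except Exception as exc:
        raise RuntimeError(f"[complexes] {exc}") from exc
    complexes = filtered.complexes
    complex_dataset.stats_table(complexes, dataset).to_csv(out("complex_stats.tsv"), sep="\t", index=False)
    summary["complexes"] = {"n_complexes": len(complexes)}

    results = None
    if config.run_enrichment:
        try:
            results, null, scheme = enrichment.run_enrichment(
                dataset, complexes, R=config.R, seed=config.seed, confidence=config.confidence
            )
        except Exception as exc:
            raise RuntimeError(f"[enrichment] {exc}") from exc
        tables = []
        for t in PTM_TYPES:
            tab = results[t].table.copy()
            tab.insert(1, "ptm_type", t)
            tab["cutoff"] = results[t].confidence
            tables.append(tab)
        header = f"# R={null.R} seed={null.seed} bins={scheme.n_bins}\n"
        with open(out("enrichment.tsv"), "w") as fh:
            fh.write(header)
            pd.concat(tables).to_csv(fh, sep="\t", index=False)
        overlaps = enrichment.overlap_enriched(results)
        overlaps["membership"].to_csv(out("enrichment_overlap.tsv"), sep="\t")
        summary["enrichment"] = {
            "selected_per_type": {t: len(results[t].selected) for t in PTM_TYPES},
            "three_plus": len(overlaps["three_plus"]),
            "ac_ub": len(overlaps["ac_ub"]),
        }

    if config.run_integration and results is not None:
        rows = []
        summary["integration"] = {}
        for t in PTM_TYPES:
            group = [cx for cx in complexes if cx.complex_id in results[t].selected]
            if not group:
                summary["integration"][t] = None
                continue
            sm = integration.group_signal_matrix(
                group, complexes, dataset, S=config.S, seed=config.seed, label=t
            )
            for which in ("observed", "mean", "sd", "z"):
                frame = sm.to_frame(which)
                frame.insert(0, "group", t)
                frame.insert(1, "quantity", which)
                rows.append(frame.reset_index(names="multiplicity"))
            summary["integration"][t] = {
                "shares": integration.composition_shares(group, dataset),
                "n_complexes": len(group),
            }
        if rows:
            pd.concat(rows).to_csv(out("signal_matrices.tsv"), sep="\t", index=False)

    if config.run_scan:
        scan = config.scan_config
        peaks = ptmi.dataset_peaks(dataset, scan)
        spots = ptmi.dataset_spots(dataset, scan)
        pd.DataFrame(
            [(w.protein_id, w.start, w.end, w.n_mods, w.ptm_density, w.styk_density, w.n_types) for w in peaks],
            columns=["protein_id", "start", "end", "n_mods", "ptm_density", "styk_density", "n_types"],
        ).to_csv(out("peaks.tsv"), sep="\t", index=False)
        # BED-like: 0-based half-open coordinates
        pd.DataFrame(
            [
                (s.protein_id, s.start - 1, s.end, f"spot_{i + 1}", round(s.density, 4), s.classification, ",".join(s.types))
                for i, s in enumerate(spots)
            ],
            columns=["protein_id", "start", "end", "spot_id", "density", "classification", "types"],
        ).to_csv(out("ptmi_spots.bed"), sep="\t", index=False)
        degrons = ptmi.find_hyperphospho_degrons(spots, dataset)
        nls = [m for p in dataset for m in ptmi.find_py_nls(p) if m.sites_in_span]
        pd.DataFrame(
            [(m.protein_id, m.start, m.end, m.motif, m.upstream10, len(m.sites_in_span), m.py_phosphorylated) for m in nls],
            columns=["protein_id", "start", "end", "motif", "upstream10", "n_sites", "py_phosphorylated"],
        ).to_csv(out("py_nls.tsv"), sep="\t", index=False)
        perm = ptmi.multi_ptm_high_density_counts(
            dataset, scan, R=config.R, seed=config.seed, mode=config.permutation_mode
        )
        summary["scan"] = {
            "n_peaks": len(peaks),
            "n_peak_proteins": len({w.protein_id for w in peaks}),
            "n_spots": len(spots),
            "n_spot_proteins": len({s.protein_id for s in spots}),
            "n_multi_spots": sum(1 for s in spots if s.classification == "multi"),
            "n_degron_candidates": len(degrons),
            "n_py_nls": len(nls),
            "high_density_windows": {
                "observed_single": perm["observed_single"],
                "observed_multi": perm["observed_multi"],
                "null_single_mean": float(perm["null_single"].mean()),
                "null_multi_mean": float(perm["null_multi"].mean()),
            },
        }

    if config.run_overlay and config.domains and config.mutations:
        try:
            domains = overlay.read_domains(config.domains)
            disorder = overlay.read_disorder(config.disorder) if config.disorder else None
            mutations, mut_log = overlay.read_mutations(config.mutations, dataset)
        except Exception as exc:
            raise RuntimeError(f"[overlay] {exc}") from exc
        table = overlay.window_classification_table(
            dataset, domains, disorder, mutations, config.scan_config, config.kappa
        )
        table.to_csv(out("window_classes.tsv"), sep="\t", index=False)
        restrict = None
        if config.tumor_ids:
            with open(config.tumor_ids) as fh:
                restrict = {line.strip() for line in fh if line.strip()}
        fractions = overlay.mutated_fraction_table(
            dataset, domains, mutations, config.scan_config, config.kappa, restrict_ids=restrict
        )
        fractions.to_csv(out("mutated_fractions.tsv"), sep="\t", index=False)
        summary["overlay"] = {
            "n_windows": len(table),
            "n_mutations_kept": len(mutations),
            "n_mutations_dropped": len(mut_log),
            "fractions": {
                f"{r.axis}:{r.category}": (None if pd.isna(r.fraction) else round(float(r.fraction), 5))
                for r in fractions.itertuples(index=False)
            },
        }

    with open(out("report.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out("run.log"), "w") as fh:
        fh.write(json.dumps(summary["config"], indent=1, sort_keys=True) + "\n")
        for line in dataset.log + filtered.log:
            fh.write(line + "\n")
    return summary
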