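# ptmnet

Coordination of post-translational modifications (PTMs) in human protein
networks: which protein complexes selectively accumulate one kind of
modification, which subunits carry that signal, and where on those proteins
modifications pile up densely enough to act as integration points.

`ptmnet` analyses four site-level modification datasets together — lysine
acetylation (Ac), serine/threonine phosphorylation (pS/T), tyrosine
phosphorylation (pY) and lysine ubiquitination (Ub) — against protein
complex membership, domain annotation, predicted disorder and cancer
mutation data. It is written for computational biologists studying PTM
crosstalk who want the full analysis reproducible from plain text tables.

## The statistics at the core

**Complex enrichment.** For a complex $c$ with members $m$ and per-member
record counts $x_m^{(t)}$ of type $t$, the two summary coordinates are the
total $T_c = \sum_m x_m^{(t)}$ and the median $M_c = \mathrm{med}_m\,
x_m^{(t)}$. The null model permutes whole per-protein modification bundles
within 16 bins (complex-frequency quartile × length quartile), keeping all
records of one protein linked; pooling $(T, M)$ over all complexes and $R =
100$ permutation replicates gives a null cloud per type. The selection
statistic is the joint exceedance

$$q_c = \frac{1}{|N|}\sum_{(T', M') \in N} \mathbf{1}\{T' \ge T_c
\wedge M' \ge M_c\},$$

and $c$ is called enriched when $q_c < 1 - \gamma$ with confidence $\gamma =
0.99$ for Ac, pY, Ub and $0.95$ for pS/T.

**Signal integration.** Member proteins of an enriched complex group are
partitioned by PTM multiplicity (number of distinct types, 1–4) and type-$t$
records summed per stratum, giving a 4×4 matrix. Each cell is scored with a
standard Z-score against $S = 1000$ random draws of equally many complexes
from the whole complex universe, localising enrichment to singly- vs
multiply-modified subunits.

**PTMi spots.** A 20-residue window slid at a 10-residue step measures local
modification density (records per residue; a lysine carrying Ac and Ub
counts twice). Windows with density $> 0.3$ — at least 7 records, hence
$2^7 = 128$ occupancy states for the minimal single-type spot — are merged
into PTMi spots, classified *single* or *multi* by the types present. A
within-protein null permutes only the type labels over the modified
positions, leaving the type-blind density profile fixed, to test whether
multi-type dense windows are enriched or depleted. Motif annotators flag
PY-NLS cores (`[RHK]-X{2,5}-P-Y`) and hyperphospho-degron candidates
(≥ 4 pS/T in a spot, ≥ 1 proline-directed, ≥ 1 Ub).

**Overlay.** Consecutive non-overlapping 20-residue windows are
cross-classified by density (high > 0.3, medium > 0.05, low > 0), maximum
domain overlap (Int 20, Lg 11–19, Sm 1–10, Ext 0 residues), disorder content
(High 20, Med 11–19, Low 1–10 disordered residues) and mutation burden
(mutated if ≥ 2 records), reproducing the domain-vs-dense-window mutation
contrast.

A fully parameterised synthetic generator (`ptmnet.synthetic`) emits every
input dialect with known ground truth — background rates with realistic type
proportions, type-pure hotspots, enriched complexes, domain/disorder/mutation
structure — so calibration and power of every stage are testable offline.

## Worked example

```
ptmnet simulate --n-proteins 120 --n-complexes 40 --seed 1 --outdir demo_data
ptmnet run-all --sites demo_data/sites.tsv --fasta demo_data/proteome.fasta \
    --complexes demo_data/complexes.tsv --domains demo_data/domains.tsv \
    --disorder demo_data/disorder.tsv --mutations demo_data/mutations.tsv \
    --outdir demo_out --seed 1
```

The simulator reports `wrote 1605 sites / 120 proteins / 40 complexes`: a
proteome whose per-type record counts (pS/T 956, Ub 243, Ac 212, pY 194)
follow the realistic ordering pS/T ≫ Ub > pY ≈ Ac, with 4 of the 40
complexes implanted with a 5× elevated pS/T rate. The run report
(`demo_out/report.json`) then shows, among other sections:

```
"enrichment": { "selected_per_type": {"Ac": 2, "Ub": 0, "pST": 6, "pY": 0}, ... }
"scan": { "n_spots": 22, "n_multi_spots": 12, "n_peaks": 795,
          "high_density_windows": {"observed_multi": 23, "null_multi_mean": 58.88,
                                   "observed_single": 47, "null_single_mean": 11.12} }
```

The pS/T selection recovers the implanted complexes (6 selected includes all
4 implanted); 22 dense PTMi spots are called across 21 proteins
(`demo_out/ptmi_spots.bed`, BED-like 0-based half-open coordinates); and the
observed count of multi-type dense windows (23) sits far below its
within-protein permutation null (mean 58.9) because the generator implants
type-pure hotspots — the same directional signature seen for real dense
regions.

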