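# Methods

## Data model and collation

The unit of counting throughout is the modification record, a unique
(protein, 1-based position, PTM type) triple. Four types are tracked: Ac and
Ub on lysine, pY on tyrosine, pS/T on serine or threonine. A lysine may carry
both an Ac and a Ub record, so a window's record density can exceed its
modifiable-residue (S/T/Y/K) density; this is deliberate and required for the
density scale to express direct acetylation:ubiquitination competition.

Site tables are anchored to sequences by a 13-residue flank centred on the
modified residue (terminal sites padded with `_`); rows whose residue, type,
position or flank disagree with the FASTA sequence are rejected row-by-row
and logged. Collation applies two rules in order: byte-identical sequences
are merged onto the lexicographically smallest identifier (site union,
deduplicated by position and type), then one isoform per gene is retained —
the one with the most records, ties again to the smallest identifier. Both
tie-breaks are arbitrary conventions chosen for determinism. Collation is
idempotent and never increases the record count. Records reported at the
same position and type with conflicting flanks are treated as inconsistent
and rejected rather than arbitrated.

## Complex statistics and the permutation null

Complexes need at least 3 unique subunits; family-expanded variants collapse
to the variant with the largest all-type record total (tie: smallest
complex id). Members with no sequence in the dataset are retained but
contribute zero records, since an unmodified subunit is informative for the
median. The median of an even-sized member-count vector is the mean of the
central pair.

The enrichment null must preserve two confounders: protein length and how
often a protein recurs across complexes, both weakly correlated with record
counts. Complex-member proteins are therefore stratified into 16 bins
(complex-frequency quartile × length quartile; values equal to a quartile
boundary go to the lower quartile) and whole per-protein record bundles are
permuted uniformly within bins, never splitting a protein's records. This
conserves, exactly and for every seed, the per-bin multiset of bundles and
global per-type totals — asserted exactly in the tests. If a covariate is
constant across proteins, its axis collapses with a logged fallback (4 bins,
or 1 when both are degenerate).

Pooling each complex's (total, median) pair over R = 100 permutation
replicates gives the null cloud. Selection uses the joint empirical
exceedance q — the fraction of null pairs at least as large in both
coordinates — rather than reconstructing 2D density contours: q is a single
monotone statistic in both coordinates that captures the same "upper-right
separation", makes the confidence cutoff explicit (select iff
q < 1 − γ), and guarantees that the γ = 0.99 selection is a subset of the
γ = 0.95 one. Per-type confidences default to 0.99 (Ac, pY, Ub) and 0.95
(pS/T), the larger pS/T dataset producing a heavier null tail. Because the
cloud pools complexes of all sizes, q is calibrated marginally over the
complex universe rather than conditionally on size; the synthetic
calibration test bounds the realised false-positive fraction at the 99%
cutoff.

## Signal-integration Z-scores

Member proteins of a selected group are deduplicated across its complexes,
unmodified members dropped, and partitioned by multiplicity (distinct types,
1–4). Cell (m, t) of the observed matrix sums type-t records over
multiplicity-m proteins. The resampling null draws S = 1000 uniform samples
of equally many complexes **without replacement** from the whole universe —
"samples of the same number of complexes" reads most naturally as distinct
complexes, and with replacement would double-count shared subunits; the
choice is configurable. Null standard deviations use the population
(n-denominator) convention, recorded in output metadata. Cells with zero
null spread report a NaN Z with an `undefined` flag, never an infinity;
|Z| > 35 carries a separate display flag.

## Window scanning and PTMi spots

Scanning uses 20-residue windows at a 10-residue step (tiled mode: step =
width). A trailing region shorter than one window after the last valid start
is not scanned. Local peaks are windows with ≥ 1 record whose density is ≥
both span-overlapping neighbours; a greedy pass in descending density
(ties leftmost) discards candidates overlapping an already-chosen peak — on
flat positive profiles this yields every other window, the maximal
non-overlapping set. Windows above density 0.3 whose spans overlap or abut
merge into PTMi spots; spot density is recomputed over the merged span, no
length cap is applied, and classification is single/multi by the types
present. Exactly 7 records are needed for a 20-residue window to exceed 0.3
(6/20 = 0.3 is not above the cutoff), giving 2^7 = 128 occupancy states for
the minimal single-type spot.

The within-protein null shuffles the multiset of type labels uniformly over
the record slots of one protein, fixing the modified positions; the
type-blind density profile and per-type counts are conserved exactly. The
default mode is the literal one — residue identity ignored, so a label can
land on a chemically impossible residue; because it is the label placement,
not chemistry, being tested this is the most stringent randomisation. A
`compatible` mode restricting exchanges to residue-class-compatible slots
(Ac/Ub among lysine slots, etc.) is provided as an option.

Grid resolution is a known limitation: a dense 20-residue region straddling
the 10-residue scan phase can split its records between two covering windows
(at most 15 residues of a worst-placed span fall in any one window), so
regions holding exactly the threshold count of 7–8 records can escape
detection when mis-aligned with the grid, while grid-aligned regions are
always caught. Raising the record count or setting `step=1` removes the
effect; the default keeps the method's native 10-residue step.

Motif rules: the PY-NLS annotator matches the tripartite core
`[RHK]X{2,5}PY` (overlapping matches enumerated) and reports the records in
the span plus whether the conserved motif tyrosine itself carries pY; the
upstream hydrophobic/basic stretch of the full consensus is not scored — the
preceding 10 residues are emitted for manual inspection instead. The
hyperphospho-degron rule retains spots with ≥ 4 pS/T records, at least one
immediately followed by proline (the [S/T]P operationalisation of
proline-directed kinase motifs), and ≥ 1 Ub record.

## Overlay classifications

Per tiled window: density bin (high > 0.3, medium > 0.05, low > 0,
unmodified; boundary values go down, so 1 record per 20-residue window is
"low"), domain class from the **maximum single-domain** overlap (Int 20,
Lg 11–19, Sm 1–10, Ext 0 residues; a union-of-domains convention is
available via config), disorder class from a precomputed binary track
(High 20, Med 11–19, Low 1–10, none 0), and a mutated flag at ≥ κ records
(default κ = 2; κ = 3 supported). Mutation records whose annotated reference
residue disagrees with the sequence are dropped and logged. The aggregated
table reports mutated-window fractions per domain class and, within
domain-external windows only, per density bin — each bin over its own window
count, with unmodified windows a separate bin, which covers both candidate
denominator readings (all external vs modified external windows).

## Synthetic study conditions

The generator emulates: lognormal protein lengths (median ≈ 400 residues),
uniform amino-acid composition by default, per-compatible-residue background
rates {Ac 0.020, pS/T 0.084, pY 0.040, Ub 0.072} — chosen to reproduce the
observed per-type record shares (roughly 56/24/13/7 % for pS/T/Ub/pY/Ac) at
≈ 0.015 records per residue overall — hotspot spans of 20–60 residues
(matching the 20–90-residue lengths of observed spots) compositionally
biased toward the compatible residues of their type and modified at rate
0.75 per compatible residue, complexes of 3–8 members sampled uniformly, and
mutations at 0.002 per residue outside domains with 3× multipliers inside
domains and inside dense windows. All stages draw from child streams of one
master seed; outputs are byte-reproducible.

What it does not emulate: sequence homology and isoform structure (collation
merge rules are exercised by hand-built fixtures instead), realistic domain
grammar, correlated placement of disorder with hotspots, and inter-protein
correlation of modification beyond complex-level rate sharing. Passing tests
therefore demonstrate calibration and power of the statistics under the
generative assumptions, not performance on any real proteome.

Calibration and power experiments fix their own conditions. The implanted-
complex recovery experiment uses 20 five-member complexes with a 5× elevated
pS/T rate (background 0.01 sites/residue, i.e. 0.10 per S/T residue at
uniform composition; 400-residue proteins) inside a universe of 200
complexes over 1000 proteins, so that elevated bundles are a small minority
of the permutation pool — mirroring real data, where enriched complexes are
a small fraction of the complex universe; in a small universe the null cloud
is contaminated by the implanted bundles themselves and sensitivity drops.
The mutation rate-ratio recovery is measured at κ = 1 in the low-rate
regime, where the mutated-window fraction is approximately linear in the
per-residue rate and the Int:Ext fraction ratio estimates the rate ratio; at
κ = 2 the fraction ratio approaches the square of the rate ratio. Problem
sizes (20 calibration repeats, 200 spot simulations, 50 mutation
simulations of 500 proteins) were chosen to make sampling error small
relative to the asserted margins.

## Numerical conventions

- Quartile boundaries via linear-interpolated quantiles; boundary values to
  the lower stratum.
- All RNG through numpy `default_rng`/`SeedSequence` children; iteration
  over sorted identifiers everywhere, so results are independent of dict or
  file ordering.
- Degenerate inputs: proteins shorter than one window yield no windows
  (logged); proteins with < 2 records return identity under type
  permutation; empty overlay categories report NaN fractions rather than 0.
- Spot output uses BED-like 0-based half-open coordinates; all internal
  coordinates are 1-based inclusive.
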