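# Methods

This note documents the models implemented in `clickdel`, their
assumptions and defaults, and what the synthetic-data generator does and
does not emulate.

## Oligonucleotide mass model

Masses are **average** (not monoisotopic), free-acid, no counterions —
the convention of vendor-reported oligo molecular weights. An oligo with
5'-OH/3'-OH termini weighs the sum of its nucleoside-monophosphate residue
masses (dA 313.21, dC 289.18, dG 329.21, dT 304.20, dU 290.17 Da; ribose
+16.00) minus 61.96 Da (loss of one HPO₃, gain of one H₂O).

Terminal/internal modification deltas live in a `ModificationTable` with
per-entry provenance. Two deltas are pinned by subtraction from measured
products of the bundled reference set: 5'-azido (+24.99 Da, azide
replacing hydroxyl) and 5'-Cy5 (+533.7 Da). The biotin-PEG4 amide label
(+473.6 Da) back-calculates from the labelled ligation product and is
chemically consistent with biotin-PEG4 acid minus water. The remaining
linker deltas (FAM, biotin-TEG, spacer-C3, amino-C6) are vendor-style
defaults; oligos carrying them are treated as consistency rows, not golden
values, because their linker masses are not independently recoverable.

CuAAC ligation conserves atoms, so a ligated product's mass is exactly
the sum of its fragment masses. Equivalently, a triazole backbone linkage
weighs +1.08 Da relative to a phosphodiester (azido 24.99 + propargyl
38.05 − 61.96); `oligo_mass` applies this per junction, which makes
`ligate_mass(a, b) == oligo_mass(a) + oligo_mass(b)` an identity rather
than an approximation.

Known data caveat: reference oligo 1's listed mass (5,732 Da) matches the
18-residue segment that appears in the ligated products, not its listed
17-residue sequence (computed 5,417.7; +1 dA gives 5,730.9). Masses are
always computed from listed sequences; the bundled TSV flags the row.
Golden-test tolerance is ±5 Da, since the source values themselves vary by
a couple of Da between text and table.

## Read-through model

Polymerase traversal of each triazole junction is Bernoulli with
probability `read_through_prob`, i.i.d. across junctions — the simplest
model consistent with single-junction stall:full measurements and with the
observed >50% full-length yield across three junctions (0.8³ ≈ 0.512).
Enzyme profiles derive from measured stall:full ratios (Pol I 3:7, Klenow
2:8, Therminator 4:6, Superscript III and 9°N 6:4), read as molar
fractions.

Junction chemistry on traversal: `rG^tr T` is copied faithfully;
`U^tr T` is deterministically copied into a single A (one template base
skipped). The deterministic skip matches the single full-length species
seen by mass; the decoder nevertheless tolerates 1–2 A gaps, since other
polymerases are known not to skip. Stalled products draw an artifact class
from configurable weights, default {correct 0.6, −A 0.3, +A 0.1}: adenosine
deletion is the dominant observed satellite and addition rarer, but the
split is not quantified experimentally — these defaults are configuration,
not measurement.

`product_spectrum` enumerates all stop/artifact combinations in closed
form (probabilities multiply and sum to 1 exactly); `full_length_fraction`
is the Monte-Carlo counterpart with a Wilson 95% binomial interval.

## Synthetic selection generator

The generator defines the study conditions for pipeline validation:

* **Library**: desk scale 50 × 20 × 20 = 20,000 trisynthons (small enough
  for exhaustive truth comparison), 13-nt codes at pairwise edit
  distance ≥ 3, 100 molecule copies per member at round 0.
* **Affinity**: independent Bernoulli capture per molecule copy;
  background 0.001, planted plane (one fixed cycle-3 block) 0.5; two
  rounds of binomial thinning. No competition, ligand depletion or PCR
  bias (amplification is uniform by design; reads are multinomial in
  post-selection counts).
* **Reads**: 10⁵ per population (naive = round 0, selected = final
  round), built from the schema layout with single-A junction gaps,
  truncated at simulated Klenow stalls (read-through 0.8 per junction;
  the 3-tag + hairpin design has 4 junctions, of which a stall at the
  final faithful junction still leaves all tags readable, so ≈1 − 0.8³ of
  reads lose tag information), uniform per-base substitution errors at
  0.005, constant Phred 30 qualities.

What this does **not** emulate: PCR jackpotting and amplification bias,
quality-score structure, indels outside junctions, context-dependent
stalling, chimeric reads, or real binding thermodynamics. Passing the
pipeline acceptance properties therefore demonstrates correctness of
decoding and enrichment arithmetic under the stated generative model, not
performance on real instrument data.

## Decoding

Reads are anchored on the hairpin-derived constant (≤1 mismatch), then
each 13-base code window is matched after trying every allowed junction
gap (1–2 A) with ≤1 substitution per code (0 indels inside codes; indel
tolerance lives only at the junction gaps, where the chemistry produces
it). With distance-3 codes this budget makes single-error decoding
provably unambiguous; equal-distance double matches are dropped as
`ambiguous`, never assigned arbitrarily. Reads that cannot cover all tag
windows are `truncated` and excluded from counts but kept in totals, so
ok + failures == reads per population. A 1-mismatch neighbourhood map
gives O(1) per-window lookup at the default budget; larger budgets fall
back to a linear scan.

## Enrichment and families

Fold enrichment divides the selected frequency by the member's naive
frequency, or by the naive average `1/diversity` when the member was never
seen naive — no pseudocounts, since that baseline is exactly the
"average of the naive library" comparison that the headline ~30,000-fold
number follows from. Each member also gets a Poisson tail
P(X ≥ k | rate = S·baseline).

Plane detection is this package's own statistic (visual inspection of the
cube plot being the classical method): members with tail < 10⁻³ are
grouped by every (cycle, block) they contain; the group with the smallest
joint log-tail (sum of member log-tails, Bonferroni-adjusted across
candidate groups) is accepted if it has ≥3 members and clears the 10⁻⁶
threshold, its members are removed, and the search repeats. Greedy
extraction prevents a single causal block from being re-reported through
every co-occurring building block; two genuinely distinct planes (e.g.
two related boronates) are reported in successive iterations. Prevalence
tables count member trisynthons, not reads.

## Numerical and design choices

* 0-based, half-open coordinates throughout; reads are processed in the
  orientation the extension simulator emits (a reverse-complement pass is
  a CLI flag).
* Tag generation is rejection sampling under an edit-distance constraint
  (edlib), deterministic per seed, with an explicit attempt budget and a
  pigeonhole fast-fail.
* The production-scale schema uses sequential placeholder codes (the real
  tag sequences are not public) and serves diversity arithmetic and layout
  derivation only.
* One seeded `numpy` generator per simulation run; seeds are recorded in
  the run metadata, and identical seeds reproduce byte-identical FASTQ.
* Acceptance-scale problem sizes: mass checks are exact and instant;
  read-through fractions use 10⁴ draws; the pipeline property runs one
  20,000-member, 2 × 10⁵-read experiment.

## Known limitations

* Per-junction i.i.d. stalling ignores any sequence-context or
  length-dependent effects.
* The ±A stall-artifact weights are unquantified defaults.
* Capture probabilities are abstract Bernoulli parameters, not binding
  constants; absolute read depths are synthetic choices.
* Plane detection assumes families are defined by a single fixed building
  block per plane; substructure-level families (shared chemotypes across
  different blocks) are out of scope.
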