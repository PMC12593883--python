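# Methods

This note records the models, parameter choices and known limits of the
`svatrx` pipeline, in the order the stages run. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Sequence model and coordinates

All intervals are 0-based half-open internally; BED output is 0-based,
VCF 1-based. A callset record carries the inserted allele without its
target-site duplication: the TSD appears once as the suffix of the left
flank and once as the prefix of the right flank, which is how an insertion
reads out of a sample assembly against the reference target site. Flanks
are ≤ 500 bp each.

## Alignment primitives

Two operations back every sequence comparison, both delegated to
Biopython's `PairwiseAligner` behind a thin result layer
(`AlignmentResult` with CIGAR-like ops and coordinate projection):

* **semi-global** — the query aligns end-to-end inside the target, target
  overhangs free. Used for whole-element vs consensus scoring.
* **local** — Smith–Waterman; all non-overlapping hits above a score
  floor, found by recursive target splitting. Targets above ~2 M DP cells
  are pre-screened with exact 13-mer seeds, so tracing a cargo across a
  multi-hundred-kilobase reference stays fast; small targets are scanned
  exhaustively, which is the regime the brute-force DP oracle in the test
  suite checks.

Scoring defaults: match +1, mismatch −1, gap of length L costs 4 + L
(affine; the "open" cost excludes the first base — the oracle uses the
identical convention). `N` never counts as a match, in score or identity.
Identity is matches / aligned columns over the core alignment, end gaps
excluded. The defaults favour ≥ 90 %-identity DNA, the regime every
pipeline comparison operates in; they are configurable via
`ScoringParams`.

## Consensus library

The packaged library is a *surrogate*: randomly composed sequences with
the true SVA architecture (hexamer CCCTCT, 300 bp Alu-like block, 15 × 37
bp VNTR, 490 bp SINE-R ending in AATAAA; F1 = 385 bp MAST2 block + 120 bp
Alu remnant + shared 3' region, junction at consensus position 385).
D/E/F diverge ~6 % in the Alu-like and SINE-R blocks; F and F1 are
identical downstream of the junction except for six diagnostic SNVs placed
in the SINE-R. The SINE-R carries the two hotspot-associated motifs at
their true offsets: GTTAAA ending 17 bp before the 233-offset cut (the
G→A substitution creates the cryptic ATTAAA signal) and AAGAAA ending
11 bp before the 323-offset cut. Bases at and just upstream of each
hotspot cut are non-A so a truncated body never blends into its tail.
AATAAA occurs exactly once per consensus, at the very end — poly-A
detection anchors on the last occurrence.

Real consensus sequences load through the same FASTA + region-TSV
interface; region boundaries for real consensuses must be supplied by the
user, since published annotations differ between libraries.

## Curation

* **TSD**: longest suffix of the left flank matching a prefix of the right
  flank with ≤ 10 % mismatches and length ≥ 5 bp (scan is longest-first,
  ties toward fewer mismatches). The 5 bp floor rejects chance flank
  agreement (expected ≤ 3 bp on random sequence) while recovering the
  simulated 4–20 bp TSD range; TSDs below the floor are not
  reconstructable from sequence and the generator does not emit them.
* **poly-A**: the tail ends at the last base before the 3' TSD (the end of
  the insertion sequence). A backward A-run walk absorbs isolated
  substitutions, stops at two consecutive non-A bases, then trims until
  the window's A-fraction reaches 0.8 and its length is ≥ 8 bp. A terminal
  AATAAA overlapping the window start is treated as the polyadenylation
  signal and the tail is counted downstream of it — this resolves the
  otherwise ambiguous boundary between the signal's own adenosines and the
  tail.
* **EN site**: the six bases spanning the inferred bottom-strand nick (two
  flank bases before the TSD plus the TSD's first four) scored as the
  fraction matching the L1 endonuclease consensus TT|AAAA. The score is
  advisory and logged, never a pass/fail criterion — the motif is
  degenerate in real data and filtering on it would over-prune.
* **reference absence**: the insertion body is locally aligned against
  ±1 kb of the insertion point; a hit with identity ≥ 0.95 covering ≥ 50 %
  of the body marks the record reference-present. The neighbourhood check
  (rather than whole-genome) keeps the step at desk scale and is the
  reason an offspring inserted far from its source never self-matches.

Pass requires TSD + poly-A + reference absence; failures carry
machine-readable reasons.

## Structure annotation

Subfamily binning uses the best **local**-alignment identity against the
D/E/F consensuses (floor 0.7, below which a record is `unclassifiable` —
the orphan-TD route). Local alignment was chosen over semi-global because
truncated ends and transduced cargo would otherwise be charged to the
consensus. Within the F bin: ≥ 20 aligned bp in the MAST2 block at ≥ 0.9
identity ⇒ F1; ≥ 20 bp of F-specific sequence upstream of the junction ⇒
F; otherwise a majority vote over the diagnostic variants covered by the
alignment, plus one optional vote from shared-TD membership; ties or zero
informative positions ⇒ `F_or_F1_ambiguous`. Abstention is deliberate —
deep 5' truncations genuinely carry no F/F1 evidence.

Segmentation anchors the consensus 5' block (everything before the VNTR)
and the SINE-R by local alignment (anchor accepted at ≥ 0.8 identity over
≥ 25 bp); the VNTR is the gap between anchors, never aligned — its copy
number varies too much for alignment there to be reliable. The hexamer
run is measured by exact unit-block extension upstream of the Alu-like
anchor: candidate periods 1–25 ranked by run length (≥ 2 exact copies),
with a single 6-mer accepted when no longer run exists. Sub-anchor
remnants (a 5' truncation leaving < 25 bp of the Alu-like block) fold into
the reported truncated-VNTR interval; this is the method's resolution
limit and the reason exact region recovery is asserted for full-length
elements and VNTR-truncated cases only.

Full length: ≥ 1 hexameric repeat plus a poly-A tail after a complete
SINE-R (D/E/F), or > 320 bp of MAST2 plus the same 3' requirement (F1).
"Complete SINE-R" tolerates small internal indels: ≥ 98 % of the consensus
SINE-R covered. The 3' truncation offset is read off the consensus
coordinate where the SINE-R alignment ends (offsets ≥ 8 bp count as
truncation); hotspots H233/H323 are assigned within ±5 bp of 233/323 and
their cryptic signals searched at the stated offsets. Untruncated
elements are additionally screened for the G→A hotspot substitution
(`cryptic_marker`).

Hexamer pattern mining decomposes each hexamer region into its minimal
repeating unit via the prefix-function period (composite 7–25-mers
reported as-is when primitive) and reports patterns shared by ≥ 5
elements.

## Transductions

5' cargo is the sequence between the 5' TSD and the body start; 3' cargo
sits between the body end (or the source's read-through internal poly-A,
detected as a ≥ 8 bp A-run after the body) and the terminal tail. Cargo
below 9 bp — the shortest credible event — is ignored. The MAST2 block of
F1 is structure, never cargo.

Origins are local hits at ≥ 0.95 identity, greedily chained along the
cargo (overlaps between adjacent chain segments are resolved in favour of
the higher-identity hit); cover < 0.8 ⇒ `untraced` but the call is kept.
Each hit is checked for a genomic poly-A in the 30 bp downstream (A
fraction ≥ 0.8 ⇒ rejected as an offspring copy rather than the origin).
Cargo under 26 bp is accepted only on a unique near-perfect hit, with one
exception: when all strong hits are the two copies of a single target-site
duplication (same chromosome, within 5 kb), the body-distal copy is the
origin — that is exactly the ultra-short TD case, a source mobilized
together with its own TSD.

Grouping unions calls whose origin segments overlap by ≥ 50 % *of the
shorter segment* on the same chromosome. Strict reciprocal overlap was
rejected because cargos copied from one source share sequence but differ
in read-through length, so the shorter is typically nested inside the
longer. A concatenated call joins a group through any of its segments.
Concatenated cargo counts as one event per side in all rates; a junction
without an intervening poly-A is flagged (`junction_polya_absent`), the
signature of template-switch events, with no further mechanism inference.

## Source elements

For each traced origin the search is directional — upstream of a 3'-TD
origin, downstream of a 5'-TD origin (an `undirected` escape hatch
exists) — within 5 kb, over three candidate sets: the reference SVA
track, an alternate-assembly point track, and the callset itself. The
nearest candidate wins; nominations within 100 bp merge into one locus.
Validation recovers the source's TSD at the cargo boundary (the cargo's
leading bases must reproduce the sequence immediately upstream of a
reference source body; for point sources tight adjacency *is* the TSD
evidence, since the cargo boundary coincides with the reference target
site). Offspring attribution goes through one segment per insertion — the
body-adjacent segment of the 3' call when present, else of the 5' call —
so every insertion belongs to exactly one source or to the lost pool.
Origins with no candidate are reported as inferred lost/low-frequency
sources.

Polymorphism: a reference source overlapping a DEL locus at ≥ 0.5
reciprocal overlap is polymorphic with element AF derived from the DEL
genotypes (element alleles = non-deleted alleles); a callset source is
polymorphic with AF from its insertion genotypes; alternate-assembly
sources have no genotype source and are treated as fixed. Per-individual
counts sum fixed sources and carried polymorphic sources; samples with
missing genotypes leave the AF denominator for that locus.

## Population statistics

AF = alternate allele count / (2 × included samples), trio offspring
excluded; a singleton is alternate allele count == 1. Records with any
missing genotype among included samples are flagged and dropped from
cohort AF tables (their AF is still reported over the full denominator).
Chi-square goodness of fit uses X² = Σ(Oᵢ−Eᵢ)²/Eᵢ with Eᵢ = pᵢ·ΣO and the
upper-tail p at k−1 degrees of freedom (scipy); expected counts of zero
are an error, below 5 a logged validity warning. Expected counts by
chromosome are length-proportional. ANOVA / Tukey HSD / t-tests are
delegated to scipy/statsmodels — re-implementing standard tests adds no
fidelity. Per-individual insertion counts use locus presence (≥ 1
allele), with the counting rule stated in the report header.

## Synthetic data

The generator's defaults are the cohort conditions the pipeline targets:
32 unrelated samples + 3 trio offspring (Mendelian transmission); 60 %
full-length elements and a 91/6/3 split of 5'/3'/both-end truncations
among the rest; hotspot split 45/45/10 between H233, H323 and off-hotspot
cuts; subfamily mixture D/E/F/F1 = 7/38/25/30 %; TSDs 4–20 bp; poly-A
tails with support 8–150 bp (median 35) and 70.5 % of tails substituted;
TD probability 0.40 with a 26.7/58.6/14.7 5'/3'/both side split, 3' cargo
about twice the 5' length (medians 258 vs 124 bp), ≥ 1 orphan, ≥ 2
ultra-short and ~12 % concatenated events; an allele-frequency spectrum
with 47 % singletons and two-thirds of mass below AF 0.05; offspring
copies mutated at 0.002 per base (never inside TSDs or tails). Genome and
element sizes are scaled to desk size — four 100 kb chromosomes, VNTRs of
10–18 units against the consensus 15 — with the subfamily VNTR-length
ordering (younger ⇒ longer) preserved.

Two properties are enforced at generation time rather than merely sampled:

* **Self-consistency** — every planted feature must be reconstructable
  from the emitted sequences alone. Sites whose TSD would not re-detect
  exactly are resampled; boundaries that are intrinsically ambiguous at
  the sequence level (a cargo whose trailing adenosines merge into the
  terminal tail, or leading adenosines into the internal tail) are
  canonicalised to the detector's boundary, truth table included. TSDs
  below the 5 bp detection floor, truncation points whose flanking
  consensus bases are adenosines, tail substitutions that would spell
  AATAAA (substituted bases are drawn from C/G), concatenation junctions
  ending in A-runs, and source TSDs starting with two adenosines are all
  excluded for the same reason: they would make the planted boundary
  formally unrecoverable, not merely hard.
* **Trio consistency** — offspring genotypes are transmitted from their
  parents, so excluding them from AF never changes a planted count.

What the generator does **not** emulate: sequencing or assembly error,
strand ambiguity, reference gaps, nested or inverted insertions, real
VNTR sequence (units are a fixed 37-mer at 5 % per-unit divergence), real
hexamer pattern diversity beyond the configured set, population structure
in the AF spectrum, or linkage between loci. Passing tests therefore
demonstrate correctness of the *inference logic* under clean composite
structures — not robustness to assembly artifacts, which real callsets
would add on top.

## Problem sizes and numerical choices

Test and acceptance cohorts use 150–200 insertions over a 400 kb genome,
which exercises every planted structure class while keeping a full
pipeline run under a minute. Alignment floors, anchor thresholds and the
±5 bp hotspot tolerance are all configurable dataclass parameters;
defaults are stated above. Degenerate inputs (empty callsets, records
with missing flanks, all-missing genotypes, zero-length chromosomes) are
handled as documented per function — failure values and warnings, never
silent exceptions, except where the input violates a type invariant.

## Known limitations

* Strand: callset sequences are assumed insertion-strand oriented;
  reverse-complemented records are supported via
  `InsertionRecord.reverse_complemented()` but not auto-detected.
* Sub-anchor 5' remnants (< 25 bp) are not separable from the truncated
  VNTR interval.
* Alternate-assembly sources have no genotypes and are classified fixed
  even when truly polymorphic in the population.
* Group comparison statistics reproduce the table layout, not specific
  published F/t values, which depend on per-element source data not
  modelled here.
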