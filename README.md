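# svatrx

Curation, structural annotation, transduction tracing and population
statistics for polymorphic SVA retrotransposon insertions.

SVAs (SINE–VNTR–*Alu* elements) are hominid-specific composite
retrotransposons and the youngest transposable-element family still
propagating in humans. A full-length element reads, 5'→3':

```
(CCCTCT)n hexamer — Alu-like — VNTR — SINE-R — poly-A
```

with the human-specific SVA_F1 subfamily replacing the hexamer and most of
the *Alu*-like region with *MAST2* exon-1 sequence. Because SVAs insert by
L1-mediated target-primed reverse transcription, each new copy is flanked
by a target-site duplication (TSD) and ends in an A-tail, and a subset
co-mobilizes flanking host sequence as 5' and/or 3' **transductions
(TDs)** — which in turn make it possible to trace offspring insertions back
to the specific **source elements** that produced them.

`svatrx` implements this analysis as a reusable pipeline over a
non-reference insertion callset (per-insertion sequence + 500 bp flanks +
per-sample genotypes):

1. **Curation** — detect TSDs (longest mismatch-tolerant flank overlap),
   poly-A tails (A-runs anchored on the terminal AATAAA signal), L1
   endonuclease site scores (TT|AAAA), and confirm the insertion is absent
   from the reference at its site.
2. **Structure annotation** — segment each element into its regions by
   anchoring the consensus 5' block and SINE-R with local alignments
   (the copy-number-variable VNTR is the gap between anchors); assign
   subfamily D/E/F/F1 (with diagnostic-variant voting for elements
   5'-truncated into the F/F1-shared region, and explicit abstention when
   no evidence survives); classify full-length vs 5'/3'/both-end truncated;
   detect the two recurrent SINE-R truncation hotspots 233 and 323 bp
   upstream of the canonical polyadenylation signal and their cryptic
   signals ((G→A)TTAAA at 23 bp, AAGAAA at 17 bp before the cut); mine
   hexamer repeat-unit patterns by minimal period.
3. **Transduction** — extract cargo enclosed within the TSDs on either side
   of the body, trace it to its origin by seeded local alignment (rejecting
   loci followed by a genomic poly-A, which are offspring copies rather
   than origins), resolve concatenated, orphan and ultra-short
   (source-TSD-only) events, and group calls by shared origin.
4. **Source elements** — nominate the SVA immediately upstream (3' TD) or
   downstream (5' TD) of each origin from the reference SVA track, an
   alternate-assembly track, or the callset itself; validate by recovering
   the source's TSD at the cargo boundary; classify fixed vs polymorphic
   against a DEL callset or insertion genotypes; count source elements per
   individual.
5. **Population statistics** — allele frequencies over 2 × 32 alleles (trio
   offspring excluded), chi-square goodness-of-fit tests with
   length-proportional or fixed expected proportions, AF spectra and
   per-individual insertion counts.

A first-class **synthetic-data module** generates a toy reference genome
plus a truth-annotated callset exhibiting every structure above, so the
whole pipeline is verifiable without any external data download. A
surrogate consensus library with the correct SVA architecture ships with
the package; real consensus sequences load through the same interface.

## Worked example

```python
from svatrx import (
    ReferenceIndex, SimulationConfig, simulate, curate_callset,
    load_default_library, annotate_structures, call_transductions,
    summarize_tds, find_source_elements, compute_af,
)

cfg = SimulationConfig(seed=11, n_insertions=80, n_decoys=5, mutation_rate=0.0)
sim = simulate(cfg)
reference = ReferenceIndex(sim.reference)

curation = curate_callset(sim.records, reference)
passing = [r for r, c in zip(sim.records, curation) if c.verdict]
print(f"curation: {len(passing)}/{len(sim.records)} pass")

structures = annotate_structures(passing, load_default_library(), curation)
full = sum(s.full_length for s in structures)
subfams = {n: sum(s.subfamily == n for s in structures) for n in ("D", "E", "F", "F1")}
print(f"full length: {full}/{len(structures)}; subfamilies: {subfams}")

calls = call_transductions(passing, structures, reference, curation, sim.annotation)
td = summarize_tds(calls, len(passing))
print(f"TD rate: {td['td_rate']:.2f} "
      f"(5' {td['n_5p_only']}, 3' {td['n_3p_only']}, both {td['n_both']}; "
      f"{td['n_concatenated']} concatenated, {td['n_orphan']} orphan)")

sources = find_source_elements(calls, sim.annotation, passing, sim.reference)
active = [s for s in sources if not s.lost]
print(f"source elements: {len(active)} ({sum(s.lost for s in sources)} lost origins)")

afs = compute_af(passing, sim.pedigree)
singletons = sum(a.singleton for a in afs if a.complete)
print(f"singletons: {singletons}/{sum(a.complete for a in afs)}")
```

Output:

```
curation: 75/80 pass
full length: 51/75; subfamilies: {'D': 6, 'E': 20, 'F': 27, 'F1': 21}
TD rate: 0.31 (5' 3, 3' 17, both 3; 3 concatenated, 1 orphan)
source elements: 10 (2 lost origins)
singletons: 35/75
```

The five reference-present decoys are the only curation failures; the 80
emitted insertions recover their planted subfamilies, truncation classes
and TD origins exactly (see `tests/`). The ten nominated source elements
are the planted active sources; the two "lost" origins are cargos planted
with no surviving source element, reported as inferred lost/low-frequency
sources.

The same stages are available from a shell via the `svatrx` CLI
(`simulate`, `curate`, `annotate`, `transduce`, `sources`, `stats`); every
report carries the seed in its header.

## Layout

```
src/svatrx/
  model.py        domain types, annotation container, interval utilities
  align.py        semi-global / local alignment primitives (seeded for big targets)
  consensus.py    subfamily consensus registry + packaged surrogate library
  io.py           FASTA / VCF / BED / TSV reading and writing
  simulate.py     synthetic reference + truth-annotated callset generator
  curation.py     TSD / poly-A / EN-site detection, reference-absence check
  structure.py    subfamily, regions, truncation hotspots, hexamer mining
  transduction.py cargo extraction, origin tracing, grouping, summaries
  sources.py      source-element nomination, validation, polymorphism
  stats.py        allele frequencies, chi-square GoF, cohort summaries
  cli.py          `svatrx` command-line interface
docs/methods.md   model, parameters and design notes
```
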