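"""Synthetic reference genome and truth-annotated SVA insertion callsets.

The generator emulates the study conditions the pipeline is meant to
recover: composite SVA insertions (hexamer / Alu-like / VNTR / SINE-R /
A-tail, or MAST2-led F1 structure) flanked by target-site duplications,
5'/3'/both-end truncations with SINE-R hotspot termination and cryptic
polyadenylation signals, substituted A-tails, 5'/3'/concatenated/orphan
transductions copied verbatim from source-element flanks in the reference,
and diploid genotypes for 32 unrelated samples plus 3 trio offspring.

Every planted feature is recorded in a :class:`TruthTable`; boundaries that
are intrinsically ambiguous at the sequence level (a transduced cargo whose
trailing adenosines merge into the terminal A-tail) are canonicalised at
generation time so that the truth is reconstructable from the emitted
sequences alone.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as svio
from .consensus import SubfamilyConsensus, load_default_library
from .curation import CurationParams, a_run_forward, detect_polya, detect_tsd
from .model import Feature, GenomeAnnotation, InsertionRecord
from .repeats import decompose_tandem

BASES = "ACGT"
_CURATION = CurationParams()


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort-level rates of the real callset this package
    models: 60% full-length elements, a 91/6/3 split of 5'/3'/both-end
    truncations, poly-A tails of 8-150 bp (median 35) with 70.5% of tails
    substituted, a 40% transduction rate with a 3'-biased side split, and an
    allele-frequency spectrum with 47% singletons.  Genome and element sizes
    are scaled to desk size (documented in the methods note).
    """

    seed: int = 0
    n_insertions: int = 200
    n_samples: int = 32
    n_trios: int = 3
    n_chromosomes: int = 4
    chromosome_length: int = 100_000
    gc_content: float = 0.41
    gene_fraction: float = 0.502
    coding_gene_fraction: float = 0.8
    te_fraction: float = 0.40
    subfamily_mixture: tuple = (("D", 0.07), ("E", 0.38), ("F", 0.25), ("F1", 0.30))
    source_subfamily_mixture: tuple = (
        ("D", 0.15),
        ("E", 0.42),
        ("F", 0.25),
        ("F1", 0.18),
    )
    tsd_length_range: tuple[int, int] = (4, 20)
    full_length_fraction: float = 0.60
    truncation_split: tuple[float, float, float] = (0.91, 0.06, 0.03)  # 5', 3', both
    hotspot_split: tuple[float, float, float] = (0.45, 0.45, 0.10)  # H233, H323, other
    hotspot_marker_fraction: float = 0.05  # untruncated elements carrying the G->A edit
    hexamer_median_bp: tuple = (("D", 111.0), ("E", 145.0), ("F", 104.0))
    hexamer_sigma: float = 0.55
    hexamer_max_bp: int = 1068
    hexamer_patterns: tuple = (
        ("CCCTCT", 0.78),
        ("CCGTCT", 0.12),
        ("CCCTCTCCGTCTGCTT", 0.10),
    )
    vntr_mean_units: tuple = (("D", 10.0), ("E", 13.0), ("F", 15.0), ("F1", 18.0))
    vntr_sd_units: float = 2.0
    vntr_min_units: int = 4
    vntr_unit_divergence: float = 0.05
    polya_median: float = 35.0
    polya_sigma: float = 0.45
    polya_range: tuple[int, int] = (8, 150)
    polya_substituted_fraction: float = 0.705
    td_probability: float = 0.40
    td_side_split: tuple[float, float, float] = (0.267, 0.586, 0.147)  # 5', 3', both
    td5_length_median: float = 124.0
    td3_length_median: float = 258.0
    td_length_sigma: float = 0.8
    td_length_range: tuple[int, int] = (25, 1200)
    concatenation_probability: float = 0.12
    orphan_td_count: int = 1
    ultra_short_count: int = 2
    lost_source_offspring: int = 2
    n_sources: int = 10
    n_alt_sources: int = 2
    n_nonref_sources: int = 2
    n_inactive_reference_sva: int = 6
    polymorphic_source_fraction: float = 0.4
    n_decoys: int = 0
    af_spectrum: tuple = ((1, 0.47), (2, 0.12), (3, 0.08))  # tail is geometric
    af_tail_geometric_p: float = 0.10
    missing_genotype_fraction: float = 0.006
    mutation_rate: float = 0.002
    en_site_fraction: float = 0.3
    validate: bool = True

    def __post_init__(self) -> None:
        for name in ("truncation_split", "hotspot_split", "td_side_split"):
            vals = getattr(self, name)
            if any(not 0 <= v <= 1 for v in vals) or abs(sum(vals) - 1) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        for name in ("subfamily_mixture", "source_subfamily_mixture"):
            probs = [p for _, p in getattr(self, name)]
            if abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("tsd_length_range", "polya_range", "td_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.n_alt_sources + self.n_nonref_sources > self.n_sources:
            raise ValueError("alt + non-reference sources exceed n_sources")
        if not 0 <= self.td_probability <= 1:
            raise ValueError("td_probability must be in [0, 1]")

    @property
    def n_reference_sources(self) -> int:
        return self.n_sources - self.n_alt_sources - self.n_nonref_sources

    @property
    def n_reference_sva(self) -> int:
        """Reference SVA loci planted in the genome (active + inactive)."""
        return self.n_reference_sources + self.n_inactive_reference_sva


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class SourceTruth:
    id: str
    provenance: str  # reference | alt_reference | non_reference_callset | lost
    subfamily: str
    chrom: str
    start: int  # body start (ref sources) or insertion point (alt / non-ref)
    end: int
    tsd: str
    tail: str
    active: bool = True
    status: str = "fixed"
    af: float | None = None
    presence: dict[str, bool] = field(default_factory=dict)
    offspring: list[str] = field(default_factory=list)

    @property
    def cargo3_anchor(self) -> int:
        """Reference coordinate where a 3' cargo copied from this source begins.

        For a reference source this is the end of the body+tail interval (the
        3' TSD copy follows it); for a point source (alt assembly or
        non-reference callset) the cargo begins at the TSD, which is the
        ``len(tsd)`` bases left of the insertion point.
        """
        return self.end if self.provenance == "reference" else self.start - len(self.tsd)

    @property
    def cargo5_anchor(self) -> int:
        """Reference coordinate where a 5' cargo copied from this source ends."""
        return self.start


@dataclass
class TruthTable:
    insertions: pd.DataFrame
    details: dict[str, dict]
    sources: pd.DataFrame
    source_details: dict[str, SourceTruth]


@dataclass
class SimulatedReference:
    config: SimulationConfig
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    ref_sources: list[SourceTruth]  # active reference sources
    alt_sources: list[SourceTruth]
    inactive_sva: list[SourceTruth]


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: dict[str, str]
    annotation: GenomeAnnotation
    records: list[InsertionRecord]
    truth: TruthTable
    samples: list[str]  # unrelated samples (AF denominator)
    all_samples: list[str]  # including trio offspring
    pedigree: dict[str, tuple[str, str]]
    sample_metadata: pd.DataFrame
    del_records: list[tuple[str, int, str, dict[str, str]]]


# ---------------------------------------------------------------------------
# small sampling helpers


def _choice(rng: np.random.Generator, pairs) -> str:
    names = [n for n, _ in pairs]
    probs = np.array([p for _, p in pairs], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _rand_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _lognormal_int(rng, median: float, sigma: float, lo: int, hi: int) -> int:
    val = int(round(float(rng.lognormal(np.log(median), sigma))))
    return int(min(hi, max(lo, val)))


def _sample_allele_count(rng, cfg: SimulationConfig) -> int:
    u = rng.random()
    acc = 0.0
    for count, prob in cfg.af_spectrum:
        acc += prob
        if u < acc:
            return count
    count = 4 + int(rng.geometric(cfg.af_tail_geometric_p)) - 1
    return min(count, 2 * cfg.n_samples - 3)


def _build_polya(rng, cfg: SimulationConfig) -> tuple[str, int]:
    """A-tail with isolated interior substitutions (C/G only, spaced >= 6 bp)."""
    length = _lognormal_int(rng, cfg.polya_median, cfg.polya_sigma, *cfg.polya_range)
    tail = ["A"] * length
    subs = 0
    if length >= 14 and rng.random() < cfg.polya_substituted_fraction:
        want = 1 + int(rng.poisson(1.0))
        want = min(want, max(1, length // 10))
        # >= 5 bp from either end and >= 6 bp apart: the running A-fraction of
        # a backward walk then never drops below 5/6, so detection is exact
        positions: list[int] = []
        candidates = list(range(5, length - 5))
        rng.shuffle(candidates)
        for pos in candidates:
            if all(abs(pos - p) >= 6 for p in positions):
                positions.append(pos)
                if len(positions) == want:
                    break
        for pos in positions:
            tail[pos] = "C" if rng.random() < 0.5 else "G"
        subs = len(positions)
    return "".join(tail), subs


# ---------------------------------------------------------------------------
# element construction


@dataclass
class PlantedElement:
    subfamily: str
    body: str
    tail: str
    tail_subs: int
    regions: dict[str, tuple[int, int]]  # on the body, present regions only
    hexamer_unit: str | None
    hexamer_units: int
    hexamer_len: int
    mast2_bp: int
    vntr_len: int | None  # None when truncated within the VNTR
    truncation: str  # none | 5p | 3p | both
    trunc3_offset: int | None
    hotspot: str  # H233 | H323 | other | none
    cryptic_signal: str  # (G->A)TTAAA | AAGAAA | none
    hotspot_marker: bool  # carries the G->A edit without truncation
    cut5_region: str | None
    cut5_offset: int | None
    f_f1_informative: bool = True


def _diverged_vntr(rng, cfg, consensus: SubfamilyConsensus, n_units: int) -> str:
    unit, _, _ = decompose_tandem(consensus.region_seq("vntr"))
    out = []
    for _ in range(n_units):
        u = list(unit)
        k = rng.binomial(len(unit), cfg.vntr_unit_divergence)
        for pos in rng.choice(len(unit), size=k, replace=False):
            alts = [b for b in BASES if b != u[pos]]
            u[pos] = alts[rng.integers(3)]
        out.append("".join(u))
    return "".join(out)


def _allowed_other_offsets(consensus: SubfamilyConsensus) -> list[int]:
    """Off-hotspot 3' cut offsets whose boundary bases keep the tail unambiguous."""
    sr = consensus.region_seq("sine_r")
    n = len(sr)
    allowed = []
    for off in range(60, 201):
        if abs(off - 233) <= 10 or abs(off - 323) <= 10:
            continue
        cut = n - off
        if cut >= 3 and "A" not in sr[cut - 2 : cut + 1]:
            allowed.append(off)
    return allowed


def build_element(
    rng,
    cfg: SimulationConfig,
    library: dict[str, SubfamilyConsensus],
    subfamily: str,
    truncation: str = "none",
    hotspot: str | None = None,
    hotspot_marker: bool = False,
) -> PlantedElement:
    cons = library[subfamily]
    hex_medians = dict(cfg.hexamer_median_bp)
    vntr_means = dict(cfg.vntr_mean_units)

    parts: list[tuple[str, str]] = []
    hexamer_unit = None
    hexamer_units = 0
    if subfamily == "F1":
        parts.append(("mast2", cons.region_seq("mast2")))
        parts.append(("alu_remnant", cons.region_seq("alu_remnant")))
    else:
        unit = _choice(rng, cfg.hexamer_patterns)
        min_units = 1 if len(unit) == 6 else 2
        target = _lognormal_int(
            rng, hex_medians[subfamily], cfg.hexamer_sigma,
            min_units * len(unit), cfg.hexamer_max_bp,
        )
        hexamer_units = max(min_units, int(round(target / len(unit))))
        hexamer_unit = unit
        parts.append(("hexamer", unit * hexamer_units))
        parts.append(("alu_like", cons.region_seq("alu_like")))
    n_units = max(cfg.vntr_min_units, int(round(rng.normal(vntr_means[subfamily], cfg.vntr_sd_units))))
    parts.append(("vntr", _diverged_vntr(rng, cfg, cons, n_units)))
    siner = cons.region_seq("sine_r")
    sr_len = len(siner)

    trunc3_offset = None
    cryptic = "none"
    hotspot_label = "none"
    if truncation in ("3p", "both"):
        hotspot = hotspot or "other"
        if hotspot == "H233":
            trunc3_offset = 233
            siner = siner[: sr_len - 233]
            s = list(siner)
            s[sr_len - 233 - 23] = "A"  # G -> A creates ATTAAA
            siner = "".join(s)
            cryptic = "(G->A)TTAAA"
        elif hotspot == "H323":
            trunc3_offset = 323
            siner = siner[: sr_len - 323]
            cryptic = "AAGAAA"
        else:
            allowed = _allowed_other_offsets(cons)
            trunc3_offset = int(allowed[rng.integers(len(allowed))])
            siner = siner[: sr_len - trunc3_offset]
        hotspot_label = hotspot
    elif hotspot_marker:
        s = list(siner)
        s[sr_len - 233 - 23] = "A"
        siner = "".join(s)
    parts.append(("sine_r", siner))

    cut5_region = None
    cut5_offset = None
    informative = True
    if truncation in ("5p", "both"):
        if subfamily == "F1":
            choices = (
                [("mast2", 0.40), ("alu_remnant", 0.10), ("vntr", 0.25), ("sine_r", 0.25)]
                if truncation == "5p"
                else [("mast2", 0.45), ("alu_remnant", 0.15), ("vntr", 0.40)]
            )
        else:
            choices = (
                [("alu_like", 0.40), ("vntr", 0.35), ("sine_r", 0.25)]
                if truncation == "5p"
                else [("alu_like", 0.5), ("vntr", 0.5)]
            )
        cut5_region = _choice(rng, choices)
        kept: list[tuple[str, str]] = []
        vntr_truncated = False
        for name, seq in parts:
            if kept:
                kept.append((name, seq))
                continue
            if name != cut5_region:
                continue
            if name == "mast2":
                off = int(rng.integers(70, 360))
            elif name == "alu_like":
                off = int(rng.integers(10, len(seq) - 10))
            elif name == "alu_remnant":
                off = int(rng.integers(5, len(seq) - 5))
            elif name == "vntr":
                off = int(rng.integers(int(0.15 * len(seq)), int(0.85 * len(seq))))
                vntr_truncated = True
            else:  # sine_r
                off = int(rng.integers(10, 441))
                if off > 410 and subfamily in ("F", "F1"):
                    informative = False
            cut5_offset = off
            kept.append((name, seq[off:]))
        parts = kept

    regions: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, seq in parts:
        if seq:
            regions[name] = (pos, pos + len(seq))
            pos += len(seq)
    body = "".join(seq for _, seq in parts)

    vntr_len = None
    if "vntr" in regions and cut5_region != "vntr":
        vntr_len = regions["vntr"][1] - regions["vntr"][0]

    tail, tail_subs = _build_polya(rng, cfg)
    hex_len = regions.get("hexamer", (0, 0))
    return PlantedElement(
        subfamily=subfamily,
        body=body,
        tail=tail,
        tail_subs=tail_subs,
        regions=regions,
        hexamer_unit=hexamer_unit if "hexamer" in regions else None,
        hexamer_units=hexamer_units if "hexamer" in regions else 0,
        hexamer_len=hex_len[1] - hex_len[0],
        mast2_bp=(regions["mast2"][1] - regions["mast2"][0]) if "mast2" in regions else 0,
        vntr_len=vntr_len,
        truncation=truncation,
        trunc3_offset=trunc3_offset,
        hotspot=hotspot_label,
        cryptic_signal=cryptic,
        hotspot_marker=hotspot_marker,
        cut5_region=cut5_region,
        cut5_offset=cut5_offset,
        f_f1_informative=informative,
    )


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(
    cfg: SimulationConfig,
    library: dict[str, SubfamilyConsensus] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedReference:
    """Toy reference genome with planted genes, TEs and reference SVA loci."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if library is None:
        library = load_default_library()
    if cfg.chromosome_length < 15_000:
        raise ValueError("chromosome too short for planted features")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    backgrounds = {
        c: rng.choice(np.array(list(BASES)), size=cfg.chromosome_length, p=p)
        for c in chroms
    }

    annotation = GenomeAnnotation()
    L = cfg.chromosome_length

    # --- place reference SVAs (active sources first) and alt-source points
    items: list[tuple[str, int]] = (
        [("ref", i) for i in range(cfg.n_reference_sources)]
        + [("inactive", i) for i in range(cfg.n_inactive_reference_sva)]
        + [("alt", i) for i in range(cfg.n_alt_sources)]
    )
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    for j, item in enumerate(items):
        per_chrom[chroms[j % len(chroms)]].append(item)

    ref_sources: list[SourceTruth] = []
    inactive: list[SourceTruth] = []
    alt_sources: list[SourceTruth] = []
    src_mix = list(cfg.source_subfamily_mixture)
    for chrom in chroms:
        todo = per_chrom[chrom]
        if not todo:
            continue
        span = L - 8000
        step = span / len(todo)
        bg = backgrounds[chrom]
        for idx, (kind, i) in enumerate(todo):
            pos = int(4000 + (idx + 0.5) * step + rng.integers(-250, 251))
            ultra = kind == "ref" and i < cfg.ultra_short_count
            lo, hi = cfg.tsd_length_range
            lo = max(lo, 5)  # a source TSD below the detection floor is unrecoverable
            t = int(rng.integers(max(lo, 12) if ultra else lo, hi + 1))
            b0 = pos
            # the internal-tail walk and ultra-short cargo boundaries must be
            # unambiguous: the TSD may not start (or, for ultra-short source
            # candidates, end) with adenosines
            for _ in range(80):
                start_ok = bg[b0 - t] != "A" and bg[b0 - t + 1] != "A"
                end_ok = (not ultra) or (bg[b0 - 2] != "A" and bg[b0 - 1] != "A")
                if start_ok and end_ok:
                    break
                b0 += 1
            tsd = "".join(bg[b0 - t : b0])
            if kind == "alt":
                src = SourceTruth(
                    id=f"alt{i:02d}",
                    provenance="alt_reference",
                    subfamily=_choice(rng, src_mix),
                    chrom=chrom,
                    start=b0,  # insertion point of the absent element
                    end=b0,
                    tsd=tsd,
                    tail=_build_polya(rng, cfg)[0],
                )
                alt_sources.append(src)
                annotation.add("alt_sva", Feature(chrom, b0, b0 + 1, src.id, src.subfamily))
                continue
            elem = build_element(rng, cfg, library, _choice(rng, src_mix), "none")
            seqfull = elem.body + elem.tail
            b1 = b0 + len(seqfull)
            bg[b0:b1] = list(seqfull)
            bg[b1 : b1 + t] = bg[b0 - t : b0]  # 3' TSD copy
            src = SourceTruth(
                id=(f"src{i:02d}" if kind == "ref" else f"rsva{i:02d}"),
                provenance="reference",
                subfamily=elem.subfamily,
                chrom=chrom,
                start=b0,
                end=b1,
                tsd=tsd,
                tail=elem.tail,
                active=(kind == "ref"),
            )
            (ref_sources if kind == "ref" else inactive).append(src)
            annotation.add("reference_sva", Feature(chrom, b0, b1, src.id, elem.subfamily))

    # --- genes / exons / UTRs: alternating gene-gap walk hits the configured
    # genic fraction by construction
    frac = cfg.gene_fraction
    for chrom in chroms:
        cursor = 0
        k = 0
        genic = 0
        while True:
            glen = int(np.clip(rng.normal(8000, 1500), 3000, 15000))
            gap = int(round(glen * (1 - frac) / frac))
            start = cursor + gap
            end = start + glen
            if end > L - 200:
                # close the chromosome with a filler gene so the realized
                # genic fraction lands on the configured value
                deficit = int(round(frac * L)) - genic
                if deficit >= 500 and cursor + 100 + deficit <= L - 100:
                    start = L - 100 - deficit
                    annotation.add(
                        "genes",
                        Feature(chrom, start, L - 100, f"gene_{chrom}_{k}", "non_coding"),
                    )
                break
            coding = rng.random() < cfg.coding_gene_fraction
            label = "protein_coding" if coding else "non_coding"
            name = f"gene_{chrom}_{k}"
            annotation.add("genes", Feature(chrom, start, end, name, label))
            genic += end - start
            n_ex = 4
            ex_positions = np.linspace(start, end - 150, n_ex).astype(int)
            for e, ex_start in enumerate(ex_positions):
                ex_label = "CDS" if coding else "exonic"
                annotation.add(
                    "exons", Feature(chrom, int(ex_start), int(ex_start) + 150, f"{name}_ex{e}", ex_label)
                )
                if coding and e == 0:
                    annotation.add("utr", Feature(chrom, int(ex_start), int(ex_start) + 50, f"{name}_utr5", "5'UTR"))
                if coding and e == n_ex - 1:
                    annotation.add("utr", Feature(chrom, int(ex_start) + 100, int(ex_start) + 150, f"{name}_utr3", "3'UTR"))
            cursor = end
            k += 1

    # --- TE intervals (labels only; overlap with genes allowed)
    te_families = [("Alu", 0.35), ("L1", 0.35), ("ERV", 0.15), ("MIR", 0.15)]
    for chrom in chroms:
        covered = 0
        k = 0
        target = cfg.te_fraction * L
        while covered < target:
            tlen = _lognormal_int(rng, 300.0, 0.6, 80, 3000)
            start = int(rng.integers(0, L - tlen))
            fam = _choice(rng, te_families)
            annotation.add("te", Feature(chrom, start, start + tlen, f"te_{chrom}_{k}", fam))
            covered += tlen
            k += 1

    sequences = {c: "".join(backgrounds[c]) for c in chroms}
    return SimulatedReference(
        config=cfg,
        sequences=sequences,
        annotation=annotation,
        ref_sources=ref_sources,
        alt_sources=alt_sources,
        inactive_sva=inactive,
    )


# ---------------------------------------------------------------------------
# genotype helpers


def _assign_genotypes(
    rng, count: int, samples: list[str], pedigree: dict[str, tuple[str, str]]
) -> dict[str, str]:
    """Distribute *count* alternate alleles over 2x len(samples) slots, then
    derive trio offspring genotypes by Mendelian transmission."""
    n = len(samples)
    slots = rng.permutation(2 * n)[:count]
    per_sample = np.zeros(n, dtype=int)
    for s in slots:
        per_sample[s // 2] += 1
    gts = {}
    for sample, c in zip(samples, per_sample):
        gts[sample] = {0: "0/0", 1: "0/1", 2: "1/1"}[int(c)]
    for child, (p1, p2) in pedigree.items():
        alleles = []
        for parent in (p1, p2):
            g = gts[parent]
            if g == "0/0":
                alleles.append(0)
            elif g == "1/1":
                alleles.append(1)
            else:
                alleles.append(int(rng.integers(2)))
        gts[child] = f"{min(alleles)}/{max(alleles)}"
    return gts


# ---------------------------------------------------------------------------
# callset simulation


def _mutate_ranges(rng, seq: list[str], ranges: list[tuple[int, int]], rate: float) -> int:
    if rate <= 0:
        return 0
    total = 0
    for lo, hi in ranges:
        n = hi - lo
        if n <= 0:
            continue
        k = rng.binomial(n, rate)
        for pos in rng.choice(n, size=k, replace=False):
            cur = seq[lo + pos]
            alts = [b for b in BASES if b != cur]
            seq[lo + pos] = alts[rng.integers(3)]
            total += k
    return total


class _SiteAllocator:
    """Samples insertion target sites under spacing/exclusion constraints."""

    def __init__(self, rng, cfg, reference: dict[str, str], forbidden: dict[str, IntervalTree]):
        self.rng = rng
        self.cfg = cfg
        self.reference = reference
        self.forbidden = forbidden
        self.chroms = sorted(reference)
        # candidate endonuclease sites: TTAAAA with the nick between TT and AAAA
        self.en_sites: list[tuple[str, int]] = []
        for chrom in self.chroms:
            seq = reference[chrom]
            i = seq.find("TTAAAA")
            while i != -1:
                self.en_sites.append((chrom, i + 2))
                i = seq.find("TTAAAA", i + 1)
        order = rng.permutation(len(self.en_sites))
        self.en_sites = [self.en_sites[i] for i in order]

    def _ok(self, chrom: str, p0: int, t: int) -> bool:
        L = len(self.reference[chrom])
        if not (600 <= p0 - t and p0 + 600 <= L):
            return False
        return not self.forbidden[chrom].overlap(p0 - t - 1, p0 + 1)

    def _claim(self, chrom: str, p0: int) -> None:
        self.forbidden[chrom].addi(p0 - 100, p0 + 100, "used")

    def _tsd_recoverable(self, chrom: str, p0: int, t: int) -> bool:
        """The planted TSD must be exactly re-detectable from the flanks."""
        ref = self.reference[chrom]
        probe = InsertionRecord(
            id="probe", chrom=chrom, pos=p0, sequence="A" * 50,
            left_flank=ref[p0 - 500 : p0], right_flank=ref[p0 - t : p0 - t + 500],
        )
        call = detect_tsd(probe, _CURATION)
        return call is not None and call.sequence == ref[p0 - t : p0] and call.mismatches == 0

    def take(self, want_en: bool) -> tuple[str, int, int, str, bool]:
        """Returns (chrom, p0, tsd_len, tsd_seq, en_planted)."""
        lo, hi = self.cfg.tsd_length_range
        # a planted TSD must be re-detectable, so lengths below the curation
        # minimum are resampled (self-consistency of the truth table)
        lo = max(lo, _CURATION.tsd_min_len)
        if want_en:
            t = int(self.rng.integers(lo, hi + 1))
            while self.en_sites:
                chrom, q = self.en_sites.pop()
                p0 = q + t
                if self._ok(chrom, p0, t) and self._tsd_recoverable(chrom, p0, t):
                    self._claim(chrom, p0)
                    return chrom, p0, t, self.reference[chrom][q : q + t], True
        for _ in range(500):
            t = int(self.rng.integers(lo, hi + 1))
            chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
            L = len(self.reference[chrom])
            p0 = int(self.rng.integers(700, L - 700))
            if self._ok(chrom, p0, t) and self._tsd_recoverable(chrom, p0, t):
                self._claim(chrom, p0)
                return chrom, p0, t, self.reference[chrom][p0 - t : p0], False
        raise RuntimeError("could not place insertion site; genome too crowded")


def simulate_source_and_offspring(
    cfg: SimulationConfig,
    simref: SimulatedReference,
    library: dict[str, SubfamilyConsensus] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Generate the callset (records + genotypes + truth) over a simulated reference."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if library is None:
        library = load_default_library()
    reference = simref.sequences
    annotation = simref.annotation

    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    offspring_samples = [f"T{i + 1:02d}" for i in range(cfg.n_trios)]
    pedigree = {
        f"T{i + 1:02d}": (f"S{2 * i + 1:02d}", f"S{2 * i + 2:02d}")
        for i in range(cfg.n_trios)
    }
    all_samples = samples + offspring_samples
    superpops = ["AFR", "AMR", "EAS", "EUR", "SAS"]
    pop_of = {}
    for i, s in enumerate(samples):
        pop_of[s] = superpops[(i // 2) % 5]  # trio parents share a population
    for child, (p1, _) in pedigree.items():
        pop_of[child] = pop_of[p1]
    sample_metadata = pd.DataFrame(
        {
            "sample": all_samples,
            "superpopulation": [pop_of[s] for s in all_samples],
            "trio_role": ["parent" if s in {p for pr in pedigree.values() for p in pr}
                          else ("offspring" if s in pedigree else "unrelated")
                          for s in all_samples],
        }
    )

    # --- forbidden zones: no insertion lands near a source locus (the
    # reference-absence check and directional source search stay clean)
    forbidden: dict[str, IntervalTree] = {c: IntervalTree() for c in reference}
    for src in simref.ref_sources + simref.inactive_sva + simref.alt_sources:
        forbidden[src.chrom].addi(src.start - 2500, src.end + 2500, src.id)
    allocator = _SiteAllocator(rng, cfg, reference, forbidden)

    # --- lost-source anchors: clean windows acting as TD origins whose source
    # element is gone from the population
    lost_handles: list[SourceTruth] = []
    for i in range(cfg.lost_source_offspring):
        for _ in range(200):
            chrom = allocator.chroms[int(rng.integers(len(allocator.chroms)))]
            L = len(reference[chrom])
            x = int(rng.integers(3000, L - 3000))
            # cargo copied from x must not begin with adenosines (they would
            # merge into the offspring's internal tail)
            if reference[chrom][x] != "A" and reference[chrom][x + 1] != "A" and not forbidden[
                chrom
            ].overlap(x - 3000, x + 3000):
                break
        forbidden[chrom].addi(x - 5500, x + cfg.td_length_range[1] + 5500, f"lost{i:02d}")
        lost_handles.append(
            SourceTruth(
                id=f"lost{i:02d}",
                provenance="lost",
                subfamily="E",
                chrom=chrom,
                start=x,
                end=x,
                tsd="",
                tail=_build_polya(rng, cfg)[0],
            )
        )

    # --- non-reference sources: ordinary full-length callset records that act
    # as source elements for other offspring
    nonref_sources: list[SourceTruth] = []
    nonref_elems: dict[str, PlantedElement] = {}
    src_mix = list(cfg.source_subfamily_mixture)
    for i in range(cfg.n_nonref_sources):
        for _ in range(100):
            chrom, p0, t, tsd, _ = allocator.take(False)
            if tsd[0] != "A" and tsd[1] != "A":  # keep cargo boundaries exact
                break
        # widen the exclusion zone like any other source locus
        forbidden[chrom].addi(p0 - 2500, p0 + 2500, f"nsrc{i:02d}")
        elem = build_element(rng, cfg, library, _choice(rng, src_mix), "none")
        src = SourceTruth(
            id=f"nsrc{i:02d}",
            provenance="non_reference_callset",
            subfamily=elem.subfamily,
            chrom=chrom,
            start=p0,
            end=p0,
            tsd=tsd,
            tail=elem.tail,
        )
        nonref_sources.append(src)
        nonref_elems[src.id] = elem

    handles = simref.ref_sources + simref.alt_sources + nonref_sources
    if not handles and cfg.td_probability > 0:
        raise ValueError("td_probability > 0 requires at least one source element")
    ultra_capable = [h for h in handles if len(h.tsd) >= 12 and h.provenance == "reference"]
    all_sources = {s.id: s for s in handles + lost_handles}

    def cargo3(src: SourceTruth, L3: int) -> tuple[str, tuple[str, int, int]]:
        a = src.cargo3_anchor
        t = len(src.tsd)
        seq = reference[src.chrom][a : a + t + L3]
        return seq, (src.chrom, a, a + t + L3)

    def cargo5(src: SourceTruth, L5: int) -> tuple[str, tuple[str, int, int]]:
        a = src.cargo5_anchor
        L5 = max(L5, len(src.tsd) + 12)
        seq = reference[src.chrom][a - L5 : a]
        return seq, (src.chrom, a - L5, a)

    # --- role schedule
    n_special = cfg.n_decoys + cfg.orphan_td_count + cfg.n_nonref_sources
    n_normal = cfg.n_insertions - n_special
    if n_normal < 0:
        raise ValueError("n_insertions too small for the configured special records")

    truth_rows: list[dict] = []
    details: dict[str, dict] = {}
    records: list[InsertionRecord] = []
    lost_remaining = list(lost_handles)
    ultra_remaining = cfg.ultra_short_count if ultra_capable else 0
    lo_td, hi_td = cfg.td_length_range

    def sample_td_len(median: float) -> int:
        return _lognormal_int(rng, median, cfg.td_length_sigma, lo_td, hi_td)

    def finish_record(
        rec_id: str,
        role: str,
        elem: PlantedElement | None,
        td5_src: SourceTruth | None,
        td3_srcs: list[SourceTruth],
        ultra_short: bool,
        want_en: bool,
        decoy: bool = False,
        fixed_site: tuple[str, int, int, str] | None = None,
    ) -> None:
        """Assemble one insertion record, canonicalise boundaries, store truth."""
        td5_src_local = td5_src
        for attempt in range(60):
            if fixed_site is not None:
                chrom, p0, t, tsd = fixed_site
                en_planted = False
            else:
                chrom, p0, t, tsd, en_planted = allocator.take(want_en and attempt < 3)
            body = elem.body if elem is not None else ""
            if decoy:
                body = reference[chrom][p0 + 50 : p0 + 950]
            tail = elem.tail if elem is not None else _build_polya(rng, cfg)[0]

            block5 = ""
            origin5: tuple[str, int, int] | None = None
            if td5_src_local is not None:
                L5 = sample_td_len(cfg.td5_length_median)
                block5, origin5 = cargo5(td5_src_local, L5)
                if elem is not None and elem.hexamer_unit and block5.endswith(elem.hexamer_unit):
                    td5_src_local = None  # cargo would merge into the hexamer run
                    block5, origin5 = "", None

            internal_tail = ""
            block3 = ""
            origins3: list[tuple[str, int, int]] = []
            if td3_srcs:
                primary = td3_srcs[0]
                if role != "orphan":
                    internal_tail = primary.tail
                segs = []
                for order, src in enumerate(td3_srcs):
                    if ultra_short and order == 0:
                        L3 = 0
                    elif role == "orphan":
                        L3 = int(rng.integers(100, 401))
                    else:
                        L3 = sample_td_len(cfg.td3_length_median)
                    seg, origin = cargo3(src, L3)
                    segs.append(seg)
                    origins3.append(origin)
                # a junction between concatenated segments must not end in
                # adenosines, or the next segment's alignment would extend
                # ambiguously into the source's genomic A-tail
                for k in range(len(segs) - 1):
                    seg = segs[k]
                    chrom3, o_start, o_end = origins3[k]
                    while len(seg) > 30 and (seg[-1] == "A" or seg[-2] == "A"):
                        seg = seg[:-1]
                        o_end -= 1
                    segs[k] = seg
                    origins3[k] = (chrom3, o_start, o_end)
                block3 = "".join(segs)

            seq_list = list(block5 + body + internal_tail + block3 + tail)
            body_start = len(block5)
            body_end = body_start + len(body)
            cargo3_start = body_end + len(internal_tail)
            tail_start_planted = cargo3_start + len(block3)
            if not decoy:
                _mutate_ranges(
                    rng,
                    seq_list,
                    [(0, body_end), (cargo3_start, tail_start_planted)],
                    cfg.mutation_rate,
                )
            sequence = "".join(seq_list)
            if len(sequence) < 50:
                continue

            left_flank = reference[chrom][p0 - 500 : p0]
            right_flank = reference[chrom][p0 - t : p0 - t + 500]
            probe = InsertionRecord(
                id=rec_id, chrom=chrom, pos=p0, sequence=sequence,
                left_flank=left_flank, right_flank=right_flank,
            )
            tsd_call = detect_tsd(probe, _CURATION)
            if tsd_call is None or tsd_call.sequence != tsd or tsd_call.mismatches:
                continue
            polya_call = detect_polya(probe, tsd_call, _CURATION)
            if polya_call is None:
                continue
            absorbed = tail_start_planted - polya_call.start
            if not (0 <= absorbed <= 6):
                continue
            if absorbed and not block3:
                continue  # the walk ate into the body: pick another layout
            # leading cargo adenosines merge into the internal tail the same
            # way trailing ones merge into the terminal tail
            absorbed_front = 0
            if internal_tail:
                run_end, _ = a_run_forward(sequence, body_end)
                absorbed_front = run_end - (body_end + len(internal_tail))
                if not (0 <= absorbed_front <= 6):
                    continue
            break
        else:
            raise RuntimeError(f"{rec_id}: could not canonicalise after 60 attempts")

        # truth boundary adjustment for absorbed cargo bases
        if absorbed and origins3:
            chrom3, o_start, o_end = origins3[-1]
            origins3[-1] = (chrom3, o_start, o_end - absorbed)
        if absorbed_front and origins3:
            chrom3, o_start, o_end = origins3[0]
            origins3[0] = (chrom3, o_start + absorbed_front, o_end)
            cargo3_start += absorbed_front
        cargo3_end = polya_call.start

        count = _sample_allele_count(rng, cfg)
        gts = _assign_genotypes(rng, count, samples, pedigree)
        missing: list[str] = []
        if rng.random() < cfg.missing_genotype_fraction:
            victim = samples[int(rng.integers(len(samples)))]
            gts[victim] = "./."
            missing.append(victim)

        record = InsertionRecord(
            id=rec_id, chrom=chrom, pos=p0, sequence=sequence,
            left_flank=left_flank, right_flank=right_flank,
            genotypes=gts, sample_pedigree=frozenset(offspring_samples),
        )
        records.append(record)

        regions_on_seq = {}
        if elem is not None:
            regions_on_seq = {
                name: (a + body_start, b + body_start) for name, (a, b) in elem.regions.items()
            }
        segments = []
        if origin5 is not None and td5_src_local is not None:
            segments.append(
                {
                    "side": "5p", "order": 0, "chrom": origin5[0],
                    "start": origin5[1], "end": origin5[2],
                    "source_id": td5_src_local.id,
                    "cargo_start": 0, "cargo_end": body_start,
                }
            )
            td5_src_local.offspring.append(rec_id)
        cursor = cargo3_start
        for order, (src, origin) in enumerate(zip(td3_srcs, origins3)):
            seg_len = origin[2] - origin[1]
            segments.append(
                {
                    "side": "3p", "order": order, "chrom": origin[0],
                    "start": origin[1], "end": origin[2], "source_id": src.id,
                    "cargo_start": cursor, "cargo_end": cursor + seg_len,
                }
            )
            cursor += seg_len
            if order == 0:
                src.offspring.append(rec_id)

        truth_rows.append(
            {
                "id": rec_id,
                "role": role,
                "chrom": chrom,
                "pos": p0,
                "subfamily": elem.subfamily if elem is not None else "",
                "truncation": elem.truncation if elem is not None else "",
                "hotspot": elem.hotspot if elem is not None else "none",
                "trunc3_offset": elem.trunc3_offset if elem is not None else None,
                "cryptic_signal": elem.cryptic_signal if elem is not None else "none",
                "hotspot_marker": bool(elem.hotspot_marker) if elem is not None else False,
                "f_f1_informative": elem.f_f1_informative if elem is not None else True,
                "tsd": tsd,
                "tsd_len": len(tsd),
                "en_planted": en_planted,
                "hexamer_unit": elem.hexamer_unit if elem is not None else None,
                "hexamer_units": elem.hexamer_units if elem is not None else 0,
                "hexamer_len": elem.hexamer_len if elem is not None else 0,
                "mast2_bp": elem.mast2_bp if elem is not None else 0,
                "vntr_len": elem.vntr_len if elem is not None else None,
                "body_start": body_start,
                "body_end": body_end,
                "internal_polya_len": (len(internal_tail) + absorbed_front) if internal_tail else 0,
                "cargo3_start": cargo3_start if block3 else None,
                "cargo3_end": cargo3_end if block3 else None,
                "polya_start": polya_call.start,
                "polya_len": polya_call.length,
                "polya_subs": polya_call.substitutions,
                "td5": td5_src_local is not None,
                "td3": bool(td3_srcs),
                "td5_len": body_start if td5_src_local is not None else 0,
                "td3_len": (cargo3_end - cargo3_start) if block3 else 0,
                "concatenated": len(td3_srcs) > 1,
                "ultra_short": ultra_short,
                "orphan": role == "orphan",
                "source_id": (
                    td3_srcs[0].id if td3_srcs else (td5_src_local.id if td5_src_local else None)
                ),
                "allele_count": count,
                "af": count / (2 * len(samples)),
                "missing_samples": ",".join(missing),
            }
        )
        details[rec_id] = {
            "regions": regions_on_seq,
            "td_segments": segments,
            "tsd": tsd,
        }

    # --- normal records (non-reference source records are built like any
    # other full-length element; their ids come first for readability)
    idx = 0
    nonref_record_ids: dict[str, str] = {}
    for src in nonref_sources:
        rec_id = f"ins{idx:04d}"
        idx += 1
        nonref_record_ids[src.id] = rec_id
        # this record IS the source element: it sits at the coordinates
        # recorded in the source truth so offspring cargo traces back to it
        finish_record(
            rec_id, "nonref_source", nonref_elems[src.id], None, [], False, False,
            fixed_site=(src.chrom, src.start, len(src.tsd), src.tsd),
        )
    for _ in range(cfg.orphan_td_count):
        rec_id = f"ins{idx:04d}"
        idx += 1
        src = handles[int(rng.integers(len(handles)))]
        finish_record(rec_id, "orphan", None, None, [src], False, False)
    for _ in range(cfg.n_decoys):
        rec_id = f"ins{idx:04d}"
        idx += 1
        finish_record(rec_id, "decoy", None, None, [], False, False, decoy=True)
    for _ in range(n_normal):
        rec_id = f"ins{idx:04d}"
        idx += 1
        subfamily = _choice(rng, list(cfg.subfamily_mixture))
        if rng.random() < cfg.full_length_fraction:
            truncation = "none"
        else:
            truncation = ("5p", "3p", "both")[
                int(rng.choice(3, p=np.array(cfg.truncation_split)))
            ]
        hotspot = None
        if truncation in ("3p", "both"):
            hotspot = ("H233", "H323", "other")[
                int(rng.choice(3, p=np.array(cfg.hotspot_split)))
            ]
        marker = (
            subfamily == "F"
            and truncation == "none"
            and rng.random() < cfg.hotspot_marker_fraction
        )
        elem = build_element(rng, cfg, library, subfamily, truncation, hotspot, marker)

        td5_src: SourceTruth | None = None
        td3_list: list[SourceTruth] = []
        ultra = False
        if rng.random() < cfg.td_probability:
            side = ("5p", "3p", "both")[int(rng.choice(3, p=np.array(cfg.td_side_split)))]
            ok5 = truncation in ("none", "3p")
            ok3 = truncation in ("none", "5p")
            # a 5'-truncated element lost any 5' cargo during integration (and
            # vice versa): resample the side among the eligible ones so the
            # overall TD rate stays at td_probability
            eligible = [
                s
                for s, p in zip(("5p", "3p", "both"), cfg.td_side_split)
                if {"5p": ok5, "3p": ok3, "both": ok5 and ok3}[s] and p > 0
            ]
            if side not in eligible and eligible:
                probs = np.array(
                    [dict(zip(("5p", "3p", "both"), cfg.td_side_split))[s] for s in eligible]
                )
                side = eligible[int(rng.choice(len(eligible), p=probs / probs.sum()))]
            want5 = side in ("5p", "both") and ok5
            want3 = side in ("3p", "both") and ok3
            if want5 or want3:
                primary = handles[int(rng.integers(len(handles)))]
                if want5:
                    td5_src = primary
                if want3:
                    if lost_remaining and not want5:
                        td3_list = [lost_remaining.pop()]
                    elif ultra_remaining and not want5:
                        primary = ultra_capable[int(rng.integers(len(ultra_capable)))]
                        td3_list = [primary]
                        ultra = True
                        ultra_remaining -= 1
                    else:
                        td3_list = [primary]
                        if rng.random() < cfg.concatenation_probability and len(handles) > 1:
                            others = [h for h in handles if h.id != primary.id]
                            td3_list.append(others[int(rng.integers(len(others)))])
        finish_record(rec_id, "sva", elem, td5_src, td3_list, ultra, rng.random() < cfg.en_site_fraction)

    # --- polymorphism status of planted sources + DEL callset
    del_records: list[tuple[str, int, str, dict[str, str]]] = []
    del_ends: dict[str, int] = {}
    for src in simref.ref_sources + simref.inactive_sva:
        if rng.random() < cfg.polymorphic_source_fraction:
            c_elem = int(rng.integers(3, 2 * len(samples) - 2))
            del_alleles = 2 * len(samples) - c_elem
            gts = _assign_genotypes(rng, del_alleles, samples, pedigree)
            src.status = "polymorphic"
            src.af = c_elem / (2 * len(samples))
            src.presence = {s: gts[s] != "1/1" for s in all_samples}
            del_id = f"DEL_{src.id}"
            del_records.append((src.chrom, src.start + 1, del_id, gts))
            del_ends[del_id] = src.end
            annotation.add("del", Feature(src.chrom, src.start, src.end, del_id))
        else:
            src.status = "fixed"
            src.presence = {s: True for s in all_samples}
    for src in simref.alt_sources:
        src.status = "fixed"
        src.presence = {s: True for s in all_samples}
    truth_by_id = {row["id"]: row for row in truth_rows}
    for src in nonref_sources:
        row = truth_by_id[nonref_record_ids[src.id]]
        rec = next(r for r in records if r.id == row["id"])
        src.status = "polymorphic"
        src.af = row["af"]
        src.presence = {s: "1" in rec.genotypes.get(s, "./.") for s in all_samples}
    # a few DEL loci unrelated to any SVA exercise the screening step
    for j in range(3):
        chrom = allocator.chroms[int(rng.integers(len(allocator.chroms)))]
        L = len(reference[chrom])
        start = int(rng.integers(1000, L - 3000))
        gts = _assign_genotypes(rng, int(rng.integers(1, 30)), samples, pedigree)
        del_id = f"DEL_misc{j}"
        del_records.append((chrom, start + 1, del_id, gts))
        del_ends[del_id] = start + int(rng.integers(200, 2000))
        annotation.add("del", Feature(chrom, start, del_ends[del_id], del_id))

    sources_all = handles + lost_handles
    sources_df = pd.DataFrame(
        [
            {
                "id": s.id,
                "provenance": s.provenance,
                "subfamily": s.subfamily,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "tsd": s.tsd,
                "active": s.active,
                "status": s.status if s.provenance != "lost" else "lost",
                "af": s.af,
                "n_offspring": len(s.offspring),
                "offspring": ",".join(s.offspring),
            }
            for s in sources_all + simref.inactive_sva
        ]
    )

    truth = TruthTable(
        insertions=pd.DataFrame(truth_rows),
        details=details,
        sources=sources_df,
        source_details={s.id: s for s in sources_all + simref.inactive_sva},
    )
    result = SimulationResult(
        config=cfg,
        reference=reference,
        annotation=annotation,
        records=records,
        truth=truth,
        samples=samples,
        all_samples=all_samples,
        pedigree=pedigree,
        sample_metadata=sample_metadata,
        del_records=del_records,
    )
    result.del_ends = del_ends  # type: ignore[attr-defined]
    if cfg.validate:
        _validate(result)
    return result


def _validate(result: SimulationResult) -> None:
    """Generation-time self-consistency: planted features must be
    reconstructable from the emitted sequences."""
    cfg = result.config
    by_id = {r.id: r for r in result.records}
    for row in result.truth.insertions.to_dict("records"):
        rec = by_id[row["id"]]
        call = detect_tsd(rec, _CURATION)
        assert call is not None and call.sequence == row["tsd"], row["id"]
        if not row["missing_samples"]:
            count = sum(
                rec.genotypes[s].count("1") for s in result.samples
            )
            assert count == row["allele_count"], row["id"]
        if cfg.mutation_rate == 0:
            for seg in result.truth.details[row["id"]]["td_segments"]:
                emitted = rec.sequence[seg["cargo_start"] : seg["cargo_end"]]
                ref_seq = result.reference[seg["chrom"]][seg["start"] : seg["end"]]
                assert emitted == ref_seq, (row["id"], seg)


def simulate(
    cfg: SimulationConfig, library: dict[str, SubfamilyConsensus] | None = None
) -> SimulationResult:
    """Full simulation: reference + callset, driven by one seeded generator."""
    if library is None:
        library = load_default_library()
    rng = np.random.default_rng(cfg.seed)
    simref = simulate_reference(cfg, library, rng)
    return simulate_source_and_offspring(cfg, simref, library, rng)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Emit reference/callset FASTA, VCFs, truth tables and annotation BEDs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "reference.fasta"
    svio.write_fasta(result.reference, paths["reference"])
    paths["callset"] = outdir / "callset.fasta"
    svio.write_callset_fasta(result.records, paths["callset"])

    contigs = {c: len(s) for c, s in result.reference.items()}
    paths["vcf"] = outdir / "genotypes.vcf"
    svio.write_genotype_vcf(
        paths["vcf"],
        [(r.chrom, r.pos, r.id, r.genotypes) for r in result.records],
        result.all_samples,
        contigs,
    )
    paths["del"] = outdir / "del_callset.vcf"
    svio.write_genotype_vcf(
        paths["del"],
        result.del_records,
        result.all_samples,
        contigs,
        ends=getattr(result, "del_ends", None),
    )

    for track in ("genes", "exons", "utr", "te", "reference_sva", "alt_sva", "del"):
        paths[track] = outdir / f"{track}.bed"
        svio.write_bed(result.annotation.features[track], paths[track])

    paths["truth_insertions"] = outdir / "truth_insertions.tsv"
    svio.write_table(result.truth.insertions, paths["truth_insertions"])
    paths["truth_sources"] = outdir / "truth_sources.tsv"
    svio.write_table(result.truth.sources, paths["truth_sources"])
    paths["truth_json"] = outdir / "truth.json"
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "details": result.truth.details,
                "pedigree": {k: list(v) for k, v in result.pedigree.items()},
            },
            fh,
            indent=1,
        )
    paths["samples"] = outdir / "samples.tsv"
    svio.write_table(result.sample_metadata, paths["samples"])
    paths["config"] = outdir / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)
    return paths
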