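"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open internally.  BED output is
emitted 0-based half-open, VCF positions 1-based, following the standard
conventions of each format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

VALID_GENOTYPES = {"0/0", "0/1", "1/1", "./."}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Validate that *seq* is non-empty uppercase ACGTN; return it."""
    if not seq:
        raise ValueError(f"{name} is empty")
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"{name} contains non-DNA characters: {bad}")
    return seq


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Interval") -> float:
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / max(1, len(self)), ov / max(1, len(other)))


@dataclass
class InsertionRecord:
    """One putative SVA insertion with its flanks and per-sample genotypes.

    ``sequence`` is the inserted allele without the target-site duplication:
    the TSD appears once as the suffix of ``left_flank`` and once as the
    prefix of ``right_flank``, mirroring how an insertion is read out of a
    sample assembly against the reference target site.
    """

    id: str
    chrom: str
    pos: int  # 1-based insertion point (base immediately left of the insert)
    sequence: str
    left_flank: str
    right_flank: str
    genotypes: dict[str, str] = field(default_factory=dict)
    sample_pedigree: frozenset[str] = frozenset()  # trio offspring to exclude

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError(f"{self.id}: flanks must be non-empty")
        if len(self.left_flank) > 500 or len(self.right_flank) > 500:
            raise ValueError(f"{self.id}: flanks must be <= 500 bp")
        if len(self.sequence) < 50:
            raise ValueError(f"{self.id}: insertion sequence must be >= 50 bp")
        bad = {g for g in self.genotypes.values()} - VALID_GENOTYPES
        if bad:
            raise ValueError(f"{self.id}: invalid genotypes {sorted(bad)}")

    def reverse_complemented(self) -> "InsertionRecord":
        """The same locus read on the opposite strand (flanks swap)."""
        return InsertionRecord(
            id=self.id,
            chrom=self.chrom,
            pos=self.pos,
            sequence=revcomp(self.sequence),
            left_flank=revcomp(self.right_flank),
            right_flank=revcomp(self.left_flank),
            genotypes=dict(self.genotypes),
            sample_pedigree=self.sample_pedigree,
        )


@dataclass(frozen=True)
class Feature:
    """A labelled interval from an annotation track."""

    chrom: str
    start: int
    end: int
    name: str
    label: str = ""  # e.g. coding/non_coding, TE family, SVA subfamily
    track: str = ""

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


class GenomeAnnotation:
    """Interval-indexed annotation tracks (genes, exons, TEs, reference SVAs, DELs)."""

    TRACKS = ("genes", "exons", "utr", "te", "reference_sva", "alt_sva", "del")

    def __init__(self) -> None:
        self._trees: dict[str, dict[str, IntervalTree]] = {t: {} for t in self.TRACKS}
        self.features: dict[str, list[Feature]] = {t: [] for t in self.TRACKS}

    def add(self, track: str, feature: Feature) -> None:
        if track not in self._trees:
            raise KeyError(f"unknown track {track!r}")
        feature = Feature(
            feature.chrom, feature.start, feature.end, feature.name, feature.label, track
        )
        self.features[track].append(feature)
        tree = self._trees[track].setdefault(feature.chrom, IntervalTree())
        if feature.end > feature.start:
            tree.addi(feature.start, feature.end, feature)
        else:  # zero-width features (insertion points) get a 1 bp footprint
            tree.addi(feature.start, feature.start + 1, feature)

    def add_all(self, track: str, features: Iterable[Feature]) -> None:
        for f in features:
            self.add(track, f)

    def query(self, track: str, chrom: str, start: int, end: int) -> list[Feature]:
        trees = self._trees[track]
        if chrom not in trees:
            # warn only for chromosomes unknown to every track
            if not any(chrom in per_track for per_track in self._trees.values()):
                warnings.warn(f"chromosome {chrom!r} unknown to the annotation; no overlap")
            return []
        hits = trees[chrom].overlap(start, max(end, start + 1))
        return sorted((h.data for h in hits), key=lambda f: (f.start, f.end, f.name))

    def chromosomes(self) -> list[str]:
        chroms: set[str] = set()
        for per_track in self._trees.values():
            chroms.update(per_track)
        return sorted(chroms)


def intersect_annotation(
    intervals: Sequence[Interval],
    annotation: GenomeAnnotation,
    track: str = "genes",
) -> list[list[tuple[Feature, int]]]:
    """Overlapping features (with overlap length) for each query interval.

    For the ``genes`` track a point query additionally resolves the exonic
    sub-context via :func:`classify_genic_context`.
    """
    out: list[list[tuple[Feature, int]]] = []
    for iv in intervals:
        hits = annotation.query(track, iv.chrom, iv.start, iv.end)
        out.append([(f, iv.overlap(f.interval)) for f in hits])
    return out


def classify_genic_context(
    annotation: GenomeAnnotation, chrom: str, pos: int
) -> tuple[str, str]:
    """Classify a 0-based point as (genic/intergenic, sub-label).

    Sub-labels: ``intronic``, ``exonic``, ``CDS``, ``5'UTR``, ``3'UTR`` or ``""``
    for intergenic points.  A point is genic iff it falls inside a gene
    interval; UTR labels override the bare exonic label when a UTR track is
    loaded.
    """
    genes = annotation.query("genes", chrom, pos, pos + 1)
    if not genes:
        return "intergenic", ""
    utrs = annotation.query("utr", chrom, pos, pos + 1)
    if utrs:
        return "genic", utrs[0].label or utrs[0].name
    exons = annotation.query("exons", chrom, pos, pos + 1)
    if exons:
        label = exons[0].label or "exonic"
        return "genic", label
    return "genic", "intronic"
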