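"""Subfamily consensus registry.

An SVA consensus is a composite of ordered regions: ``hexamer`` (CCCTCT
repeat), ``alu_like``, ``vntr`` and ``sine_r`` for subfamilies D/E/F, with
the terminal AATAAA polyadenylation signal at the very end of the SINE-R.
The human-specific F1 subfamily replaces the hexamer and most of the
Alu-like region with MAST2 exon-1 sequence: its regions are ``mast2``,
``alu_remnant``, ``vntr`` and ``sine_r``, and the MAST2/SVA splice junction
sits at a fixed consensus coordinate (385 in the packaged library).

F and F1 are identical downstream of the junction apart from a small set of
diagnostic single-nucleotide variants, which allow subfamily assignment of
elements 5'-truncated into the shared 3' region.

A packaged surrogate library (randomly composed sequences with the correct
architecture) ships with the package; real consensus sequences with a
user-supplied region table load through the same interface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import check_dna

SUBFAMILIES = ("D", "E", "F", "F1")
REGION_ORDER = {
    "D": ("hexamer", "alu_like", "vntr", "sine_r"),
    "E": ("hexamer", "alu_like", "vntr", "sine_r"),
    "F": ("hexamer", "alu_like", "vntr", "sine_r"),
    "F1": ("mast2", "alu_remnant", "vntr", "sine_r"),
}

CANONICAL_POLYA_SIGNAL = "AATAAA"


@dataclass
class DiagnosticVariant:
    """A position in the shared 3' region distinguishing F from F1."""

    position: int  # on this consensus's own coordinate system
    f_allele: str
    f1_allele: str


@dataclass
class SubfamilyConsensus:
    name: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    canonical_polya_signal: tuple[int, int]
    mast2_junction: int | None = None
    diagnostic_variants: list[DiagnosticVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_dna(self.sequence, f"consensus {self.name}")
        expected = REGION_ORDER.get(self.name)
        if expected is not None:
            missing = [r for r in expected if r not in self.regions]
            if missing:
                raise ValueError(f"consensus {self.name}: missing region rows {missing}")
        prev_end = 0
        for region, (start, end) in self.regions.items():
            if start < prev_end:
                raise ValueError(
                    f"consensus {self.name}: region {region!r} overlaps or is out of order"
                )
            if start != prev_end:
                raise ValueError(
                    f"consensus {self.name}: gap before region {region!r} "
                    f"(regions must tile the consensus)"
                )
            prev_end = end
        if prev_end != len(self.sequence):
            raise ValueError(
                f"consensus {self.name}: regions end at {prev_end}, "
                f"sequence length {len(self.sequence)}"
            )
        sig_start, sig_end = self.canonical_polya_signal
        sr_start, sr_end = self.regions["sine_r"]
        # inside the SINE-R, or immediately downstream of it
        if not (sr_start <= sig_start and sig_end <= sr_end + (sig_end - sig_start)):
            raise ValueError(
                f"consensus {self.name}: polyadenylation signal outside SINE-R"
            )
        if (self.name == "F1") != (self.mast2_junction is not None):
            raise ValueError(
                f"consensus {self.name}: mast2_junction must be set iff subfamily is F1"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_seq(self, region: str) -> str:
        start, end = self.regions[region]
        return self.sequence[start:end]

    @property
    def five_prime_anchor(self) -> tuple[int, int]:
        """Consensus interval of the 5' anchor block (everything before the VNTR)."""
        return (0, self.regions["vntr"][0])

    @property
    def signal_end(self) -> int:
        return self.canonical_polya_signal[1]


def load_consensus_library(
    fasta_path: str | Path, regions_path: str | Path
) -> dict[str, SubfamilyConsensus]:
    """Load a consensus library from a FASTA and a region-boundary TSV.

    The TSV has columns ``subfamily, feature, name, start, end, note`` with
    feature rows ``region`` (tiling intervals), ``signal`` (the canonical
    polyadenylation signal), ``junction`` (F1 only) and ``diagnostic``
    (note ``F=<base>;F1=<base>``, coordinates on the F1 consensus).
    """
    with open(fasta_path) as handle:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    table = pd.read_csv(regions_path, sep="\t", dtype={"subfamily": str, "name": str})
    required = {"subfamily", "feature", "name", "start", "end", "note"}
    if not required.issubset(table.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")

    library: dict[str, SubfamilyConsensus] = {}
    diagnostics_f1: list[DiagnosticVariant] = []
    for _, row in table[table.feature == "diagnostic"].iterrows():
        alleles = dict(part.split("=") for part in str(row.note).split(";"))
        diagnostics_f1.append(
            DiagnosticVariant(int(row.start), alleles["F"], alleles["F1"])
        )
    diagnostics_f1.sort(key=lambda d: d.position)

    for subfamily in sorted(sequences):
        sub = table[table.subfamily == subfamily]
        regions: dict[str, tuple[int, int]] = {}
        for region in REGION_ORDER.get(subfamily, ()):  # enforce canonical order
            rows = sub[(sub.feature == "region") & (sub.name == region)]
            if rows.empty:
                raise ValueError(
                    f"consensus {subfamily}: region row {region!r} missing from table"
                )
            r = rows.iloc[0]
            regions[region] = (int(r.start), int(r.end))
        signal_rows = sub[sub.feature == "signal"]
        if signal_rows.empty:
            raise ValueError(f"consensus {subfamily}: polyadenylation signal row missing")
        sig = signal_rows.iloc[0]
        junction = None
        if subfamily == "F1":
            jrows = sub[sub.feature == "junction"]
            if jrows.empty:
                raise ValueError("consensus F1: mast2 junction row missing")
            junction = int(jrows.iloc[0].start)
        library[subfamily] = SubfamilyConsensus(
            name=subfamily,
            sequence=sequences[subfamily],
            regions=regions,
            canonical_polya_signal=(int(sig.start), int(sig.end)),
            mast2_junction=junction,
            diagnostic_variants=[],
        )

    # attach diagnostic variants: stored on F1 coordinates, mapped to F by the
    # length offset of the two consensuses (identical downstream of the junction)
    if "F1" in library and "F" in library and diagnostics_f1:
        offset = len(library["F"]) - len(library["F1"])
        library["F1"].diagnostic_variants = diagnostics_f1
        library["F"].diagnostic_variants = [
            DiagnosticVariant(d.position + offset, d.f_allele, d.f1_allele)
            for d in diagnostics_f1
        ]
        for name, cons in (("F", library["F"]), ("F1", library["F1"])):
            allele_attr = "f_allele" if name == "F" else "f1_allele"
            for d in cons.diagnostic_variants:
                expected = getattr(d, allele_attr)
                actual = cons.sequence[d.position]
                if actual != expected:
                    raise ValueError(
                        f"consensus {name}: diagnostic allele mismatch at "
                        f"{d.position} (table {expected}, sequence {actual})"
                    )
    return library


def default_library_paths() -> tuple[Path, Path]:
    data = importlib.resources.files("svatrx") / "data"
    return Path(str(data / "sva_consensus.fasta")), Path(str(data / "sva_consensus_regions.tsv"))


def load_default_library() -> dict[str, SubfamilyConsensus]:
    """The packaged surrogate consensus library (subfamilies D, E, F, F1)."""
    fasta, regions = default_library_paths()
    return load_consensus_library(fasta, regions)
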