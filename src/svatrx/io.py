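"""File I/O for callsets, annotation tracks and reports.

Formats: FASTA for sequences (callset records use the id convention
``<id>|L`` / ``<id>`` / ``<id>|R`` for left flank, insertion and right
flank), VCF for genotypes and the DEL callset, BED6 for annotation tracks,
TSV for tabular reports.  Intervals are 0-based half-open internally and in
BED; VCF positions are 1-based.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .model import Feature, GenomeAnnotation, InsertionRecord

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_callset_fasta(records: Sequence[InsertionRecord], path: str | Path) -> None:
    """Write insertions with their flanks using the ``id|L / id / id|R`` convention."""
    seqs: dict[str, str] = {}
    for rec in records:
        seqs[f"{rec.id}|L"] = rec.left_flank
        seqs[rec.id] = rec.sequence
        seqs[f"{rec.id}|R"] = rec.right_flank
    write_fasta(seqs, path)


_CALLSET_ID = re.compile(r"^(?P<id>.+?)(?:\|(?P<part>[LR]))?$")


def read_callset_fasta(
    path: str | Path,
    genotypes: Mapping[str, Mapping[str, str]] | None = None,
    positions: Mapping[str, tuple[str, int]] | None = None,
    pedigree: Iterable[str] = (),
) -> list[InsertionRecord]:
    """Read a callset FASTA following the flank naming convention.

    ``positions`` maps insertion id to (chrom, 1-based pos); ids without an
    entry get a placeholder coordinate.  ``genotypes`` maps insertion id to a
    per-sample genotype dict (e.g. parsed from a VCF with
    :func:`read_genotype_vcf`).
    """
    raw = read_fasta(path)
    parts: dict[str, dict[str, str]] = {}
    for name, seq in raw.items():
        m = _CALLSET_ID.match(name)
        rec_id = m.group("id")
        part = m.group("part") or "I"
        parts.setdefault(rec_id, {})[part] = seq
    records = []
    ped = frozenset(pedigree)
    for rec_id in sorted(parts):
        p = parts[rec_id]
        if set(p) != {"L", "I", "R"}:
            raise ValueError(
                f"callset record {rec_id!r}: expected '{rec_id}|L', '{rec_id}', "
                f"'{rec_id}|R', found parts {sorted(p)}"
            )
        chrom, pos = (positions or {}).get(rec_id, ("unknown", 1))
        records.append(
            InsertionRecord(
                id=rec_id,
                chrom=chrom,
                pos=pos,
                sequence=p["I"],
                left_flank=p["L"],
                right_flank=p["R"],
                genotypes=dict((genotypes or {}).get(rec_id, {})),
                sample_pedigree=ped,
            )
        )
    return records


# ---------------------------------------------------------------------------
# BED


def write_bed(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as BED6 (name column ``name``, score 0, strand '+');
    the feature label rides in column 7 when present."""
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.name)):
            cols = [f.chrom, str(f.start), str(f.end), f.name, "0", "+"]
            if f.label:
                cols.append(f.label)
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path, track: str = "") -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            label = cols[6] if len(cols) > 6 else ""
            name = cols[3] if len(cols) > 3 else ""
            features.append(
                Feature(cols[0], int(cols[1]), int(cols[2]), name, label, track)
            )
    return features


def load_annotation(tracks: Mapping[str, str | Path]) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from a mapping of track name to BED path."""
    ann = GenomeAnnotation()
    for track, path in tracks.items():
        ann.add_all(track, read_bed(path, track=track))
    return ann


# ---------------------------------------------------------------------------
# VCF


def write_genotype_vcf(
    path: str | Path,
    records: Sequence[tuple[str, int, str, dict[str, str]]],
    samples: Sequence[str],
    contigs: Mapping[str, int],
    source: str = "svatrx",
    ends: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal genotype VCF.

    ``records`` holds (chrom, 1-based pos, id, per-sample genotype) tuples;
    symbolic ``<INS>``/``<DEL>`` alleles keep the file small — sequences live
    in the callset FASTA.  ``ends`` optionally maps record ids to 0-based
    interval ends, emitted as ``INFO/END`` (1-based inclusive).
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##ALT=<ID=INS,Description="Insertion relative to the reference">',
        '##ALT=<ID=DEL,Description="Deletion relative to the reference">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant interval">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, rec_id, gts in records:
        alt = "<DEL>" if rec_id.startswith("DEL") else "<INS>"
        info = "."
        if ends is not None and rec_id in ends:
            info = f"END={ends[rec_id]}"
        row = [chrom, str(pos), rec_id, "N", alt, ".", "PASS", info, "GT"]
        row += [gts.get(s, "./.") for s in samples]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_vcf(path: str | Path) -> tuple[dict[str, dict[str, str]], dict[str, tuple[str, int]]]:
    """Parse a genotype VCF into (id -> sample -> GT, id -> (chrom, pos))."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    genotypes: dict[str, dict[str, str]] = {}
    positions: dict[str, tuple[str, int]] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}_{variant.POS}"
        gts = {}
        for sample, g in zip(samples, variant.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                gts[sample] = "./."
            else:
                gts[sample] = "/".join(str(a) for a in sorted(alleles))
        genotypes[vid] = gts
        positions[vid] = (variant.CHROM, variant.POS)
    vcf.close()
    return genotypes, positions


# ---------------------------------------------------------------------------
# TSV reports


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """TSV report; optional metadata (tool version, seed) rides in # headers."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
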