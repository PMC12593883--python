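"""Source-element nomination, validation and polymorphism classification.

A source element is an SVA locus shown to be retrotranspositionally active
through the transductions of its offspring: for a 3' TD the source sits
immediately upstream of the cargo's origin locus, for a 5' TD immediately
downstream.  Candidates are searched in the reference SVA track, an
alternate-assembly track and the non-reference callset itself, validated by
recovering the source's own target-site duplication at the cargo boundary,
and classified fixed vs polymorphic by screening against a DEL callset (for
reference elements) or the insertion genotypes (for non-reference ones).
Origins with no SVA within the search window are reported as inferred
lost/low-frequency sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import GenomeAnnotation, InsertionRecord, Interval
from .transduction import OriginLocus, TransductionCall


@dataclass(frozen=True)
class SourceParams:
    window: int = 5000  # directional search distance from the TD origin
    adjacency_tol: int = 50
    merge_distance: int = 100  # nominations closer than this are one locus
    del_min_reciprocal: float = 0.5
    tsd_match_min: int = 5
    undirected: bool = False


@dataclass
class SourceElement:
    id: str
    chrom: str
    start: int
    end: int
    provenance: str  # reference | alt_reference | non_reference_callset | lost
    subfamily: str = ""
    validated_by_source_tsd: bool = False
    status: str = "unknown"  # fixed | polymorphic
    af: float | None = None
    offspring: list[str] = field(default_factory=list)
    presence: dict[str, bool] = field(default_factory=dict)

    @property
    def lost(self) -> bool:
        return self.provenance == "lost"


def _validate_source_tsd(
    cargo: str, side: str, reference: dict[str, str], chrom: str, s: int, e: int, params
) -> bool:
    """Find the source's TSD at the cargo boundary.

    For a 3' cargo the leading bases must reproduce the sequence immediately
    upstream of the source body (the 5' TSD copy); for a 5' cargo the
    trailing bases must reproduce the sequence immediately downstream (the
    3' TSD copy).
    """
    seq = reference.get(chrom)
    if seq is None:
        return False
    for k in range(25, params.tsd_match_min - 1, -1):
        if side == "3p":
            if s - k >= 0 and len(cargo) >= k and cargo[:k] == seq[s - k : s]:
                return True
        else:
            if e + k <= len(seq) and len(cargo) >= k and cargo[-k:] == seq[e : e + k]:
                return True
    return False


def _candidates(
    origin: OriginLocus,
    side: str,
    annotation: GenomeAnnotation,
    callset_points: dict[str, tuple[str, int]],
    skip_record: str,
    params: SourceParams,
) -> list[tuple[int, str, str, int, int, str]]:
    """(distance, provenance, id, start, end, subfamily) candidates near an origin."""
    out = []
    directions = ["up", "down"] if params.undirected else (
        ["up"] if side == "3p" else ["down"]
    )
    lo = origin.start - params.window
    hi = origin.end + params.window
    for f in annotation.query("reference_sva", origin.chrom, lo, hi):
        for d in directions:
            dist = origin.start - f.end if d == "up" else f.start - origin.end
            if -params.adjacency_tol <= dist <= params.window:
                out.append((abs(dist), "reference", f.name, f.start, f.end, f.label))
    for f in annotation.query("alt_sva", origin.chrom, lo, hi):
        point = f.start
        for d in directions:
            dist = origin.start - point if d == "up" else point - origin.end
            if -params.adjacency_tol <= dist <= params.window:
                out.append((abs(dist), "alt_reference", f.name, point, point, f.label))
    for rid, (chrom, pos) in callset_points.items():
        if rid == skip_record or chrom != origin.chrom:
            continue
        for d in directions:
            dist = origin.start - pos if d == "up" else pos - origin.end
            if -params.adjacency_tol <= dist <= params.window:
                out.append((abs(dist), "non_reference_callset", rid, pos, pos, ""))
    out.sort()
    return out


def find_source_elements(
    td_calls: list[TransductionCall],
    annotation: GenomeAnnotation,
    records: list[InsertionRecord],
    reference: dict[str, str],
    params: SourceParams = SourceParams(),
) -> list[SourceElement]:
    """Nominate source elements from TD origins.

    Every traced origin segment nominates a candidate; offspring are
    attributed through one segment per insertion (the body-adjacent segment
    of the 3' call when present, else of the 5' call), so each insertion
    belongs to exactly one source or to the lost pool.  Nominations within
    ``merge_distance`` of each other collapse into one locus.
    """
    callset_points = {r.id: (r.chrom, r.pos) for r in records}
    by_key: dict[tuple, SourceElement] = {}
    lost: list[SourceElement] = []
    lost_n = 0

    calls_by_insertion: dict[str, list[TransductionCall]] = {}
    for c in td_calls:
        if c.origins and not c.untraced:
            calls_by_insertion.setdefault(c.insertion_id, []).append(c)

    def nominate(call: TransductionCall, origin: OriginLocus, owner: bool) -> None:
        nonlocal lost_n
        cands = _candidates(
            origin, call.side, annotation, callset_points, call.insertion_id, params
        )
        if not cands:
            if owner:
                lost_n += 1
                le = SourceElement(
                    id=f"lost{lost_n:02d}",
                    chrom=origin.chrom,
                    start=origin.start if call.side == "3p" else origin.end,
                    end=origin.start if call.side == "3p" else origin.end,
                    provenance="lost",
                    offspring=[call.insertion_id],
                )
                lost.append(le)
            return
        dist, provenance, name, s, e, subfam = cands[0]
        # merge nominations of (nearly) the same locus
        key = None
        for existing in by_key:
            if existing[0] == origin.chrom and abs(existing[1] - s) <= params.merge_distance:
                key = existing
                break
        if key is None:
            key = (origin.chrom, s)
            by_key[key] = SourceElement(
                id=name, chrom=origin.chrom, start=s, end=e,
                provenance=provenance, subfamily=subfam,
            )
        src = by_key[key]
        seg_cargo = (
            call.cargo[origin.cargo_start :]
            if call.side == "3p"
            else call.cargo[: origin.cargo_end]
        )
        if provenance == "reference":
            if _validate_source_tsd(seg_cargo, call.side, reference, origin.chrom, s, e, params):
                src.validated_by_source_tsd = True
        elif dist <= 25:
            # for point sources (alt assembly / callset) the cargo boundary IS
            # the reference target site, so tight adjacency is the TSD evidence
            src.validated_by_source_tsd = True
        if owner and call.insertion_id not in src.offspring:
            src.offspring.append(call.insertion_id)

    for insertion_id in sorted(calls_by_insertion):
        calls = calls_by_insertion[insertion_id]
        owner_call = next((c for c in calls if c.side == "3p"), calls[0])
        for call in calls:
            for k, origin in enumerate(call.origins):
                # the body-adjacent segment: first for 3' cargo, last for 5'
                primary = (k == 0) if call.side == "3p" else (k == len(call.origins) - 1)
                nominate(call, origin, owner=(call is owner_call and primary))
    return sorted(by_key.values(), key=lambda s: (s.chrom, s.start)) + lost


def classify_polymorphism(
    sources: list[SourceElement],
    annotation: GenomeAnnotation,
    del_genotypes: dict[str, dict[str, str]],
    records: list[InsertionRecord],
    samples: list[str],
) -> None:
    """Assign fixed/polymorphic status, allele frequency and presence vectors.

    A reference source overlapping a DEL locus (reciprocal overlap >= 0.5)
    is polymorphic with the element AF derived from the DEL genotypes; a
    non-reference source is polymorphic with AF from its insertion
    genotypes; anything else is fixed (present in every sample).  Samples
    with missing genotypes are dropped from that locus's AF denominator.
    """
    rec_by_pos = {(r.chrom, r.pos): r for r in records}
    for src in sources:
        if src.lost:
            continue
        if src.provenance == "reference":
            dels = annotation.query("del", src.chrom, src.start, src.end)
            match = None
            locus = Interval(src.chrom, src.start, src.end)
            for f in dels:
                if locus.reciprocal_overlap(f.interval) >= 0.5:
                    match = f
                    break
            if match is not None and match.name in del_genotypes:
                gts = del_genotypes[match.name]
                alleles = present = 0
                for s in samples:
                    g = gts.get(s, "./.")
                    if g == "./.":
                        continue
                    alleles += 2
                    present += 2 - g.count("1")  # element alleles = non-deleted
                src.status = "polymorphic"
                src.af = present / alleles if alleles else None
                src.presence = {s: gts.get(s, "./.") != "1/1" for s in samples}
            else:
                src.status = "fixed"
                src.presence = {s: True for s in samples}
        elif src.provenance == "non_reference_callset":
            rec = rec_by_pos.get((src.chrom, src.start))
            if rec is None:
                rec = next((r for r in records if r.id == src.id), None)
            if rec is None:
                src.status = "fixed"
                src.presence = {s: True for s in samples}
                continue
            alleles = alt = 0
            for s in samples:
                g = rec.genotypes.get(s, "./.")
                if g == "./.":
                    continue
                alleles += 2
                alt += g.count("1")
            src.status = "polymorphic"
            src.af = alt / alleles if alleles else None
            src.presence = {s: "1" in rec.genotypes.get(s, "") for s in samples}
        else:  # alt_reference: no genotype source, treated as fixed
            src.status = "fixed"
            src.presence = {s: True for s in samples}


def count_sources_per_individual(
    sources: list[SourceElement], samples: list[str]
) -> pd.DataFrame:
    """Per-sample source-element counts (fixed + carried polymorphic loci)."""
    rows = []
    usable = [s for s in sources if not s.lost]
    for sample in samples:
        count = sum(1 for s in usable if s.presence.get(sample, True))
        rows.append({"sample": sample, "n_sources": count})
    return pd.DataFrame(rows)


def sources_table(sources: list[SourceElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "provenance": s.provenance,
                "subfamily": s.subfamily,
                "validated_by_source_tsd": s.validated_by_source_tsd,
                "status": s.status,
                "af": s.af,
                "n_offspring": len(s.offspring),
                "offspring": ",".join(s.offspring),
            }
            for s in sources
        ]
    )
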