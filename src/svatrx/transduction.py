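"""Transduction (TD) detection, origin tracing and grouping.

A transduction is non-SVA genomic sequence co-mobilized with an insertion:
5' cargo lies between the 5' TSD and the element body (transcription from
an upstream start site), 3' cargo between the body (or its internal poly-A,
when the source's own tail was read through) and the terminal poly-A
(polyadenylation-signal readthrough).  Cargo is traced back to its origin
by local alignment against the reference; the true origin lacks a genomic
poly-A immediately downstream of the match, which distinguishes it from
other offspring copies of the same cargo.  Cargo covered by segments from
multiple loci is a concatenated TD; cargo with no SVA body at all is an
orphan TD; cargo matching just the source's target-site duplication is an
ultra-short TD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ReferenceIndex, ScoringParams, align_local
from .curation import CurationResult, a_run_forward
from .model import GenomeAnnotation, InsertionRecord, Interval, classify_genic_context
from .structure import UNCLASSIFIABLE, StructureAnnotation


@dataclass(frozen=True)
class TransductionParams:
    min_cargo: int = 9  # shortest credible cargo, bp
    min_identity: float = 0.95
    min_cover: float = 0.8
    polya_check_window: int = 30
    polya_check_fraction: float = 0.8
    ultra_short_max: int = 25
    short_cargo_bp: int = 26  # below this, only unique near-perfect hits count
    min_reciprocal: float = 0.5
    max_chain_overlap: float = 0.2
    scoring: ScoringParams = ScoringParams()


@dataclass
class OriginLocus:
    chrom: str
    start: int
    end: int
    identity: float
    strand: str = "+"
    cargo_start: int = 0
    cargo_end: int = 0


@dataclass
class TransductionCall:
    insertion_id: str
    side: str  # 5p | 3p
    cargo: str
    cargo_interval: tuple[int, int]
    origins: list[OriginLocus] = field(default_factory=list)
    untraced: bool = False
    orphan: bool = False
    ultra_short_source_tsd: bool = False
    junction_polya_absent: bool = False
    group: str | None = None
    context: dict = field(default_factory=dict)

    @property
    def concatenated(self) -> bool:
        return len(self.origins) > 1

    def __post_init__(self) -> None:
        if self.side not in ("5p", "3p"):
            raise ValueError(f"invalid side {self.side!r}")


# ---------------------------------------------------------------------------
# candidate extraction


def extract_td_candidates(
    record: InsertionRecord,
    structure: StructureAnnotation,
    curation: CurationResult | None = None,
    params: TransductionParams = TransductionParams(),
) -> list[TransductionCall]:
    """Cargo candidates on either side of the SVA body.

    An insertion whose entire body is non-SVA cargo plus a tail is an orphan
    candidate.  The MAST2 block of an F1 element is part of the standard F1
    structure and never counts as 5' cargo.
    """
    seq = record.sequence
    polya_iv = structure.regions.get("polya")
    polya_start = polya_iv[0] if polya_iv else len(seq)
    calls: list[TransductionCall] = []

    if structure.subfamily == UNCLASSIFIABLE:
        ok = curation is None or (curation.tsd is not None and curation.polya is not None)
        if ok and polya_start >= params.min_cargo:
            calls.append(
                TransductionCall(
                    insertion_id=record.id,
                    side="3p",
                    cargo=seq[:polya_start],
                    cargo_interval=(0, polya_start),
                    orphan=True,
                )
            )
        return calls

    body_start, body_end = structure.body_interval
    if body_start >= params.min_cargo:
        calls.append(
            TransductionCall(
                insertion_id=record.id,
                side="5p",
                cargo=seq[:body_start],
                cargo_interval=(0, body_start),
            )
        )
    cargo3_start = body_end
    internal_end, _ = a_run_forward(seq, body_end)
    if internal_end - body_end >= 8:
        cargo3_start = internal_end  # the source's own read-through tail
    if polya_start - cargo3_start >= params.min_cargo:
        calls.append(
            TransductionCall(
                insertion_id=record.id,
                side="3p",
                cargo=seq[cargo3_start:polya_start],
                cargo_interval=(cargo3_start, polya_start),
                junction_polya_absent=(internal_end - body_end) < 8,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# origin tracing


def _polya_at_origin(reference: ReferenceIndex, chrom: str, end: int, params) -> bool:
    seq = reference.sequences[chrom]
    window = seq[end : end + params.polya_check_window]
    if len(window) < 10:
        return False
    return window.count("A") / len(window) >= params.polya_check_fraction


def trace_origin(
    cargo: str,
    reference: ReferenceIndex | dict[str, str],
    params: TransductionParams = TransductionParams(),
    side: str | None = None,
) -> tuple[list[OriginLocus], bool]:
    """Trace a cargo to its origin locus (or loci).

    Local hits with identity >= ``min_identity`` are chained greedily along
    the cargo into a minimal cover; hits followed by a genomic poly-A are
    rejected as offspring copies.  Short cargo (< 20 bp) is accepted only on
    a unique near-perfect hit — except when all hits are the two copies of
    one target-site duplication (same chromosome, within a few kb): an
    ultra-short TD matches both TSD copies of its source, and the origin is
    the body-distal copy (downstream for 3' cargo, upstream for 5').
    Returns (ordered origin segments, untraced).
    """
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(dict(reference))
    floor = min(0.9 * len(cargo), 22.0) * params.scoring.match
    hits = align_local(cargo, reference, params.scoring, score_floor=floor, max_hits=30)
    hits = [h for h in hits if h.identity >= params.min_identity]
    hits = [
        h for h in hits if not _polya_at_origin(reference, h.target_name, h.target_end, params)
    ]
    if len(cargo) < params.short_cargo_bp:
        strong = [
            h
            for h in hits
            if h.identity >= 0.98 and (h.query_end - h.query_start) >= 0.9 * len(cargo)
        ]
        if len(strong) > 1 and side is not None:
            chroms = {h.target_name for h in strong}
            span = max(h.target_end for h in strong) - min(h.target_start for h in strong)
            if len(chroms) == 1 and span <= 5000:
                strong.sort(key=lambda h: h.target_start)
                strong = [strong[-1] if side == "3p" else strong[0]]
        if len(strong) != 1:
            return [], True
        hits = strong
    accepted = []
    covered = np.zeros(len(cargo), dtype=bool)
    for h in hits:  # already sorted by score desc
        span = covered[h.query_start : h.query_end]
        if span.sum() > params.max_chain_overlap * (h.query_end - h.query_start):
            continue
        accepted.append(h)
        covered[h.query_start : h.query_end] = True
    cover = covered.mean() if len(cargo) else 0.0
    accepted.sort(key=lambda h: h.query_start)
    # a hit can bleed a few sloppy columns across a concatenation junction;
    # resolve overlaps in favour of the higher-identity segment
    for i in range(1, len(accepted)):
        a, b = accepted[i - 1], accepted[i]
        overlap = a.query_end - b.query_start
        if overlap > 0:
            if a.identity >= b.identity:
                _trim_query_left(b, overlap)
            else:
                _trim_query_right(a, overlap)
    origins = [
        OriginLocus(
            chrom=h.target_name,
            start=h.target_start,
            end=h.target_end,
            identity=round(h.identity, 4),
            cargo_start=h.query_start,
            cargo_end=h.query_end,
        )
        for h in accepted
    ]
    return origins, cover < params.min_cover


def _trim_query_right(hit, n_query: int) -> None:
    """Drop the trailing alignment columns consuming *n_query* query bases."""
    remaining = n_query
    ops = hit.ops
    while ops and remaining > 0:
        op, n = ops[-1]
        if op == "D":  # target-only: drop with the trimmed tail
            hit.target_end -= n
            ops.pop()
            continue
        take = min(n, remaining)
        hit.query_end -= take
        if op == "M":
            hit.target_end -= take
        remaining -= take
        if take == n:
            ops.pop()
        else:
            ops[-1] = (op, n - take)
    while ops and ops[-1][0] == "D":
        hit.target_end -= ops.pop()[1]


def _trim_query_left(hit, n_query: int) -> None:
    remaining = n_query
    ops = hit.ops
    while ops and remaining > 0:
        op, n = ops[0]
        if op == "D":
            hit.target_start += n
            ops.pop(0)
            continue
        take = min(n, remaining)
        hit.query_start += take
        if op == "M":
            hit.target_start += take
        remaining -= take
        if take == n:
            ops.pop(0)
        else:
            ops[0] = (op, n - take)
    while ops and ops[0][0] == "D":
        hit.target_start += ops.pop(0)[1]


# ---------------------------------------------------------------------------
# pipeline


def call_transductions(
    records: list[InsertionRecord],
    structures: list[StructureAnnotation],
    reference: ReferenceIndex | dict[str, str],
    curations: list[CurationResult] | None = None,
    annotation: GenomeAnnotation | None = None,
    params: TransductionParams = TransductionParams(),
) -> list[TransductionCall]:
    """Extract, trace, flag and group transductions for a callset."""
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(dict(reference))
    struct_by_id = {s.insertion_id: s for s in structures}
    cur_by_id = {c.insertion_id: c for c in curations or []}
    point_of_record = {r.id: (r.chrom, r.pos) for r in records}

    calls: list[TransductionCall] = []
    for record in records:
        structure = struct_by_id.get(record.id)
        if structure is None:
            continue
        for call in extract_td_candidates(record, structure, cur_by_id.get(record.id), params):
            call.origins, call.untraced = trace_origin(call.cargo, reference, params, call.side)
            if call.origins and len(call.cargo) <= params.ultra_short_max:
                call.ultra_short_source_tsd = _adjacent_to_sva(
                    call, annotation, point_of_record
                )
            if annotation is not None and call.origins:
                top = call.origins[0]
                genic, sub = classify_genic_context(
                    annotation, top.chrom, (top.start + top.end) // 2
                )
                tes = annotation.query("te", top.chrom, top.start, top.end)
                call.context = {
                    "genic": genic,
                    "sublabel": sub,
                    "te_families": sorted({f.label for f in tes}),
                }
            calls.append(call)
    group_tds(calls, params)
    return calls


def _adjacent_to_sva(call, annotation, point_of_record, slack: int = 8) -> bool:
    """Does the cargo origin abut an SVA locus on the body side?"""
    top = call.origins[0]
    anchor = top.start if call.side == "3p" else top.end
    if annotation is not None:
        for track, attr in (("reference_sva", "end"), ("alt_sva", "start")):
            for f in annotation.query(track, top.chrom, anchor - slack, anchor + slack):
                edge = f.end if attr == "end" else f.start
                if abs(edge - anchor) <= slack:
                    return True
    for rid, (chrom, pos) in point_of_record.items():
        if rid != call.insertion_id and chrom == top.chrom and abs(pos - anchor) <= slack + 20:
            return True
    return False


def group_tds(
    calls: list[TransductionCall], params: TransductionParams = TransductionParams()
) -> dict[str, list[TransductionCall]]:
    """Partition TD calls into shared-origin groups (union-find).

    Two calls share a group when any of their origin segments overlap on the
    same chromosome by >= ``min_reciprocal`` of the shorter segment (cargos
    copied from one source share sequence but differ in read-through length,
    so the shorter is typically nested in the longer); this lets a
    concatenated call join a group through any of its segments.  Size-one
    groups are singletons (``group`` stays None).
    """
    traced = [c for c in calls if c.origins]
    parent = list(range(len(traced)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(traced)):
        for j in range(i + 1, len(traced)):
            hit = False
            for a in traced[i].origins:
                for b in traced[j].origins:
                    ia = Interval(a.chrom, a.start, a.end)
                    ib = Interval(b.chrom, b.start, b.end)
                    shorter = max(1, min(len(ia), len(ib)))
                    if ia.overlap(ib) / shorter >= params.min_reciprocal:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                union(i, j)

    members: dict[int, list[TransductionCall]] = {}
    for i, call in enumerate(traced):
        members.setdefault(find(i), []).append(call)
    groups: dict[str, list[TransductionCall]] = {}
    next_id = 1
    for root in sorted(members):
        group = members[root]
        if len(group) < 2:
            group[0].group = None
            continue
        gid = f"G{next_id:02d}"
        next_id += 1
        for call in group:
            call.group = gid
        groups[gid] = group
    return groups


# ---------------------------------------------------------------------------
# cohort summary


def summarize_tds(calls: list[TransductionCall], n_records: int) -> dict:
    """Per-side event counts, rates, lengths and context fractions.

    A concatenated cargo counts as one event for its side; an insertion with
    cargo on both sides contributes to the ``both`` category.
    """
    by_insertion: dict[str, set[str]] = {}
    for c in calls:
        by_insertion.setdefault(c.insertion_id, set()).add(c.side)
    n5_only = sum(1 for s in by_insertion.values() if s == {"5p"})
    n3_only = sum(1 for s in by_insertion.values() if s == {"3p"})
    n_both = sum(1 for s in by_insertion.values() if s == {"5p", "3p"})
    n_with_td = len(by_insertion)

    lengths = {"5p": [], "3p": []}
    for c in calls:
        lengths[c.side].append(len(c.cargo))
    genic = [c for c in calls if c.context]
    return {
        "n_records": n_records,
        "n_with_td": n_with_td,
        "td_rate": n_with_td / n_records if n_records else np.nan,
        "n_5p_only": n5_only,
        "n_3p_only": n3_only,
        "n_both": n_both,
        "n_none": n_records - n_with_td,
        "ratio_3p_to_5p": (n3_only / n5_only) if n5_only else np.nan,
        "len_5p_mean": float(np.mean(lengths["5p"])) if lengths["5p"] else np.nan,
        "len_5p_median": float(np.median(lengths["5p"])) if lengths["5p"] else np.nan,
        "len_3p_mean": float(np.mean(lengths["3p"])) if lengths["3p"] else np.nan,
        "len_3p_median": float(np.median(lengths["3p"])) if lengths["3p"] else np.nan,
        "n_concatenated": sum(1 for c in calls if c.concatenated),
        "n_orphan": sum(1 for c in calls if c.orphan),
        "n_ultra_short": sum(1 for c in calls if c.ultra_short_source_tsd),
        "n_untraced": sum(1 for c in calls if c.untraced),
        "genic_origin_fraction": (
            float(np.mean([c.context.get("genic") == "genic" for c in genic]))
            if genic
            else np.nan
        ),
        "te_origin_fraction": (
            float(np.mean([bool(c.context.get("te_families")) for c in genic]))
            if genic
            else np.nan
        ),
    }


def calls_table(calls: list[TransductionCall]) -> pd.DataFrame:
    """One row per origin segment (concatenated segments as ordered sub-rows)."""
    rows = []
    for c in calls:
        base = {
            "insertion_id": c.insertion_id,
            "side": c.side,
            "cargo_start": c.cargo_interval[0],
            "cargo_end": c.cargo_interval[1],
            "cargo_len": len(c.cargo),
            "orphan": c.orphan,
            "concatenated": c.concatenated,
            "ultra_short_source_tsd": c.ultra_short_source_tsd,
            "untraced": c.untraced,
            "group": c.group or "",
        }
        if not c.origins:
            rows.append({**base, "segment": 0, "chrom": "", "start": -1, "end": -1, "identity": np.nan})
        for k, o in enumerate(c.origins):
            rows.append(
                {
                    **base,
                    "segment": k,
                    "chrom": o.chrom,
                    "start": o.start,
                    "end": o.end,
                    "identity": o.identity,
                }
            )
    return pd.DataFrame(rows)
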