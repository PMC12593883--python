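"""Structural annotation of curated SVA insertions.

Each insertion is segmented into its composite regions (hexamer or MAST2
block, Alu-like, VNTR, SINE-R, poly-A) by anchoring the 5' and 3' consensus
blocks with local alignments and treating the copy-number-variable VNTR as
the gap between anchors.  Subfamily assignment proceeds in two stages:
D/E/F binning by best local-alignment identity, then F vs F1 resolution via
MAST2 presence, diagnostic single-nucleotide variants in the shared 3'
region, and (optionally) shared-transduction membership.  Recurrent 3'
truncation hotspots in the SINE-R and their associated cryptic
polyadenylation signals are detected at fixed consensus offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentResult, ScoringParams, align_local
from .consensus import SubfamilyConsensus
from .curation import CurationParams, CurationResult, PolyACall, detect_polya
from .model import InsertionRecord
from .repeats import count_unit_copies_backward, minimal_period

AMBIGUOUS = "F_or_F1_ambiguous"
UNCLASSIFIABLE = "unclassifiable"

# SINE-R truncation hotspots: (offset of the cut upstream of the canonical
# signal end, cryptic signal motif, motif offset upstream of the cut)
HOTSPOTS = {
    "H233": (233, "ATTAAA", 23),  # (G->A)TTAAA
    "H323": (323, "AAGAAA", 17),
}


@dataclass(frozen=True)
class StructureParams:
    min_bin_identity: float = 0.7
    anchor_min_identity: float = 0.80
    anchor_min_bp: int = 25
    mast2_min_identity: float = 0.9
    mast2_min_bp: int = 20
    mast2_full_length_bp: int = 320
    sine_r_complete_cover: float = 0.98
    trunc3_min_offset: int = 8
    hotspot_tolerance: int = 5
    hexamer_max_period: int = 25
    scoring: ScoringParams = ScoringParams()


@dataclass
class StructureAnnotation:
    insertion_id: str
    subfamily: str  # D | E | F | F1 | F_or_F1_ambiguous | unclassifiable
    evidence: dict = field(default_factory=dict)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    full_length: bool = False
    truncation: str = "none"  # none | 5p | 3p | both
    truncation_offset_3prime: int | None = None
    hotspot: str = "none"
    cryptic_signal: str = "none"
    cryptic_signal_found: bool = False
    cryptic_marker: bool = False  # hotspot substitution without truncation
    hexamer_unit: str | None = None
    hexamer_length: int = 0
    mast2_bp: int = 0
    vntr_length: int | None = None
    polya_length: int = 0
    polya_substitutions: int = 0
    body_interval: tuple[int, int] = (0, 0)


def _aligned_base(hit: AlignmentResult, seq: str, target_pos: int) -> str | None:
    """Base of the query aligned to *target_pos*, or None at gaps/outside."""
    if not (hit.target_start <= target_pos < hit.target_end):
        return None
    q, t = hit.query_start, hit.target_start
    for op, n in hit.ops:
        if op == "M":
            if target_pos < t + n:
                return seq[q + (target_pos - t)]
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            if target_pos < t + n:
                return None
            t += n
    return None


def _best_local(query: str, target: str, params: StructureParams) -> AlignmentResult | None:
    floor = min(len(query), len(target), params.anchor_min_bp) * params.scoring.match * 0.8
    hits = align_local(query, target, params.scoring, score_floor=floor, max_hits=3)
    return hits[0] if hits else None


def _aligned_bp_in(hit: AlignmentResult, lo: int, hi: int) -> tuple[int, int]:
    """(aligned bp, matches-proxy) of the hit inside query interval [lo, hi)."""
    q, t = hit.query_start, hit.target_start
    bp = 0
    for op, n in hit.ops:
        if op == "M":
            overlap = max(0, min(q + n, hi) - max(q, lo))
            bp += overlap
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            t += n
    return bp, bp


def classify_subfamily(
    record: InsertionRecord,
    consensuses: dict[str, SubfamilyConsensus],
    td_context: dict[str, str] | None = None,
    params: StructureParams = StructureParams(),
) -> tuple[str, dict]:
    """Assign a subfamily with its supporting evidence.

    Binning into D/E/F uses the best local-alignment identity against each
    subfamily consensus (local alignment tolerates truncated ends and
    transduced cargo).  Within the F bin, elements extending upstream of the
    MAST2/SVA splice junction are F1 iff that upstream part aligns to the
    MAST2 block; elements 5'-truncated into the shared 3' region are voted
    on diagnostic variants plus shared-transduction membership; no decisive
    vote yields ``F_or_F1_ambiguous``.
    """
    seq = record.sequence
    evidence: dict = {"identity": {}}
    best_bin, best_hit, best_score = None, None, -np.inf
    for name in ("D", "E", "F"):
        # query the consensus against the insertion so coordinate maps are
        # expressed on consensus positions
        hit = _best_local(consensuses[name].sequence, seq, params)
        if hit is None:
            continue
        evidence["identity"][name] = round(hit.identity, 4)
        if hit.score > best_score:
            best_bin, best_hit, best_score = name, hit, hit.score
    if best_hit is None or best_hit.identity < params.min_bin_identity:
        return UNCLASSIFIABLE, evidence
    if best_bin in ("D", "E"):
        return best_bin, evidence

    # --- F vs F1
    f1 = consensuses["F1"]
    f = consensuses["F"]
    hit1 = _best_local(f1.sequence, seq, params)
    junction = f1.mast2_junction or 0
    mast2_bp = 0
    if hit1 is not None:
        evidence["identity"]["F1"] = round(hit1.identity, 4)
        # note: here the consensus is the query, so query coordinates are
        # consensus coordinates
        mast2_bp = max(0, min(hit1.query_end, junction) - hit1.query_start)
    evidence["mast2_bp"] = mast2_bp
    if mast2_bp >= params.mast2_min_bp and hit1 is not None and hit1.identity >= params.mast2_min_identity:
        return "F1", evidence

    # does the element carry F-specific sequence upstream of the junction?
    junction_on_f = len(f.sequence) - (len(f1.sequence) - junction)
    f_upstream_bp = max(0, min(best_hit.query_end, junction_on_f) - best_hit.query_start)
    evidence["f_upstream_bp"] = f_upstream_bp
    if f_upstream_bp >= params.mast2_min_bp:
        return "F", evidence

    # --- 5'-truncated into the shared region: diagnostic variant vote
    votes_f = votes_f1 = 0
    for dv in f.diagnostic_variants:
        # best_hit has the F consensus as query: map consensus pos -> insertion
        base = None
        if best_hit.query_start <= dv.position < best_hit.query_end:
            base = _aligned_base(_swap_hit(best_hit), seq, dv.position)
        if base == dv.f_allele:
            votes_f += 1
        elif base == dv.f1_allele:
            votes_f1 += 1
    td_vote = (td_context or {}).get(record.id)
    if td_vote == "F":
        votes_f += 1
    elif td_vote == "F1":
        votes_f1 += 1
    evidence["diagnostic_votes"] = {"F": votes_f, "F1": votes_f1}
    if votes_f1 > votes_f:
        return "F1", evidence
    if votes_f > votes_f1:
        return "F", evidence
    return AMBIGUOUS, evidence


def _swap_hit(hit: AlignmentResult) -> AlignmentResult:
    """View an alignment with query and target roles exchanged."""
    swapped = AlignmentResult(
        query_start=hit.target_start,
        query_end=hit.target_end,
        target_start=hit.query_start,
        target_end=hit.query_end,
        identity=hit.identity,
        score=hit.score,
        ops=[("M" if op == "M" else ("D" if op == "I" else "I"), n) for op, n in hit.ops],
    )
    return swapped


def _detect_hexamer_run(seq: str, j: int, params: StructureParams) -> tuple[int, str | None, int]:
    """Tandem run of a <=25 bp unit ending at *j*: (start, unit, copies).

    Candidate periods are ranked by run length (>= 2 exact copies); a single
    6-mer immediately upstream is accepted as a one-unit hexamer when no
    longer run exists.
    """
    best = (j, None, 0)  # start, unit, copies
    best_len = 0
    for p in range(1, min(params.hexamer_max_period, j) + 1):
        unit = seq[j - p : j]
        if p > 1 and minimal_period(unit) < p and p % minimal_period(unit) == 0:
            continue  # non-primitive unit; counted at its own period
        copies = count_unit_copies_backward(seq, j, unit)
        if copies >= 2 and copies * p > best_len:
            best = (j - copies * p, unit, copies)
            best_len = copies * p
    if best[1] is None and j >= 6:
        return j - 6, seq[j - 6 : j], 1
    return best


def segment_regions(
    record: InsertionRecord,
    consensus: SubfamilyConsensus,
    polya: PolyACall | None = None,
    params: StructureParams = StructureParams(),
) -> dict:
    """Locate region intervals on the insertion by consensus anchoring.

    The 5' anchor is the consensus block upstream of the VNTR (hexamer +
    Alu-like, or MAST2 + Alu remnant for F1); the 3' anchor is the SINE-R.
    The VNTR is the gap between anchors.  Returns a dict with ``regions``
    plus anchor bookkeeping used by length/hotspot classification.
    """
    if polya is None:
        polya = detect_polya(record, None, CurationParams())
    seq = record.sequence
    core_end = polya.start if polya is not None else len(seq)
    core = seq[:core_end]
    if len(core) < 20:
        raise ValueError(f"{record.id}: no aligned body upstream of the poly-A tail")

    siner = consensus.region_seq("sine_r")
    sr_len = len(siner)
    hit3 = _best_local(siner, core, params)
    if hit3 is not None and (
        hit3.identity < params.anchor_min_identity
        or hit3.query_end - hit3.query_start < params.anchor_min_bp
    ):
        hit3 = None

    anchor_lo, anchor_hi = consensus.five_prime_anchor
    anchor_seq = consensus.sequence[anchor_lo:anchor_hi]
    search_end = hit3.target_start if hit3 is not None else len(core)
    hit5 = _best_local(anchor_seq, core[:search_end], params) if search_end >= 20 else None
    if hit5 is not None and (
        hit5.identity < params.anchor_min_identity
        or hit5.query_end - hit5.query_start < params.anchor_min_bp
    ):
        hit5 = None

    regions: dict[str, tuple[int, int]] = {}
    hexamer_unit = None
    hexamer_copies = 0
    body_start = 0
    mast2_bp = 0
    if hit5 is not None:
        if consensus.name == "F1":
            body_start = hit5.target_start
            j385 = consensus.mast2_junction or 0
            mast2_bp = max(0, min(hit5.query_end, j385) - hit5.query_start)
            if mast2_bp:
                split = hit5.map_query_to_target(j385)
                regions["mast2"] = (hit5.target_start, split)
                regions["alu_remnant"] = (split, hit5.target_end)
            else:
                regions["alu_remnant"] = (hit5.target_start, hit5.target_end)
        else:
            alu_start_cons = consensus.regions["alu_like"][0]
            if hit5.query_start <= alu_start_cons:
                j = hit5.map_query_to_target(alu_start_cons)
            else:
                j = hit5.target_start
            run_start, hexamer_unit, hexamer_copies = _detect_hexamer_run(core, j, params)
            if hexamer_copies:
                regions["hexamer"] = (run_start, j)
                body_start = run_start
            else:
                body_start = j
            regions["alu_like"] = (j, hit5.target_end)
        if hit3 is not None and hit3.target_start > hit5.target_end:
            regions["vntr"] = (hit5.target_end, hit3.target_start)
    elif hit3 is not None and hit3.target_start > 0:
        # 5' anchor gone but sequence remains upstream of the SINE-R: a
        # 5'-truncated element carries no 5' cargo, so this is a truncated
        # VNTR remnant
        regions["vntr"] = (0, hit3.target_start)
        body_start = 0
    if hit3 is not None:
        regions["sine_r"] = (hit3.target_start, hit3.target_end)
    if polya is not None:
        regions["polya"] = (polya.start, polya.end)

    cons3_start = hit3.query_start if hit3 is not None else None
    cons3_end = hit3.query_end if hit3 is not None else None
    return {
        "regions": regions,
        "hit5": hit5,
        "hit3": hit3,
        "body_start": body_start,
        "hexamer_unit": hexamer_unit,
        "hexamer_copies": hexamer_copies,
        "mast2_bp": mast2_bp,
        "sine_r_cons_interval": (cons3_start, cons3_end),
        "sine_r_len": sr_len,
        "polya": polya,
    }


def classify_length(
    seg: dict,
    consensus: SubfamilyConsensus,
    params: StructureParams = StructureParams(),
) -> tuple[bool, str, int | None]:
    """(full_length, truncation class, 3' truncation offset).

    Full length for D/E/F requires at least one hexameric repeat at the 5'
    end plus a poly-A tail after a complete SINE-R; for F1, more than 320 bp
    of MAST2 sequence plus the same 3' requirement.
    """
    sr_len = seg["sine_r_len"]
    cons3_start, cons3_end = seg["sine_r_cons_interval"]
    polya_ok = seg["polya"] is not None

    offset3: int | None = None
    if cons3_end is None:
        offset3 = sr_len  # no SINE-R at all: treated as 3'-truncated body
    else:
        off = sr_len - cons3_end
        if off >= params.trunc3_min_offset:
            offset3 = off
    t3 = offset3 is not None

    if consensus.name == "F1":
        five_intact = seg["mast2_bp"] > params.mast2_full_length_bp
    else:
        five_intact = seg["hexamer_copies"] >= 1
    t5 = not five_intact

    sine_r_complete = (
        cons3_end is not None
        and cons3_start is not None
        and (cons3_end - cons3_start) >= params.sine_r_complete_cover * sr_len
        and not t3
    )
    full = five_intact and sine_r_complete and polya_ok
    if full:
        return True, "none", None
    if t5 and t3:
        return False, "both", offset3
    if t5:
        return False, "5p", offset3
    if t3:
        return False, "3p", offset3
    return False, "none", offset3


def detect_truncation_hotspots(
    record: InsertionRecord,
    seg: dict,
    offset3: int | None,
    params: StructureParams = StructureParams(),
) -> tuple[str, str, bool]:
    """(hotspot id, cryptic signal, signal found) for a 3'-truncated element.

    The two recurrent SINE-R termination sites lie 233 and 323 bp upstream
    of the canonical polyadenylation signal's last base; their cryptic
    signals sit 23 bp ((G->A)TTAAA) and 17 bp (AAGAAA) before the
    termination point.
    """
    if offset3 is None or seg["hit3"] is None:
        return "none", "none", False
    body_end = seg["hit3"].target_end
    for name, (off, motif, motif_off) in HOTSPOTS.items():
        if abs(offset3 - off) <= params.hotspot_tolerance:
            lo = body_end - motif_off
            window = record.sequence[max(0, lo - 2) : lo + len(motif) + 2]
            return name, motif if name == "H323" else "(G->A)TTAAA", motif in window
    return "none", "none", False


def detect_cryptic_marker(record: InsertionRecord, seg: dict) -> bool:
    """True when an untruncated element carries the (G->A)TTAAA substitution."""
    hit3 = seg["hit3"]
    if hit3 is None:
        return False
    sr_len = seg["sine_r_len"]
    pos = sr_len - 233 - 23  # the G of GTTAAA on the SINE-R
    if not (hit3.query_start <= pos < hit3.query_end):
        return False
    base = _aligned_base(_swap_hit(hit3), record.sequence, pos)
    return base == "A"


def annotate_structure(
    record: InsertionRecord,
    consensuses: dict[str, SubfamilyConsensus],
    curation: CurationResult | None = None,
    td_context: dict[str, str] | None = None,
    params: StructureParams = StructureParams(),
) -> StructureAnnotation:
    """Full structural annotation of one curated insertion."""
    subfamily, evidence = classify_subfamily(record, consensuses, td_context, params)
    polya = curation.polya if curation is not None else None
    if subfamily == UNCLASSIFIABLE:
        if polya is None:
            polya = detect_polya(record)
        ann = StructureAnnotation(record.id, subfamily, evidence)
        if polya is not None:
            ann.regions["polya"] = (polya.start, polya.end)
            ann.polya_length = polya.length
            ann.polya_substitutions = polya.substitutions
        return ann
    cons = consensuses[subfamily if subfamily in consensuses else "F"]
    seg = segment_regions(record, cons, polya, params)
    full, trunc, offset3 = classify_length(seg, cons, params)
    hotspot, cryptic, cryptic_found = detect_truncation_hotspots(record, seg, offset3, params)
    marker = False
    if offset3 is None:
        marker = detect_cryptic_marker(record, seg)

    hex_iv = seg["regions"].get("hexamer")
    vntr_iv = seg["regions"].get("vntr")
    vntr_length = None
    if vntr_iv is not None and seg["hit5"] is not None and seg["hit3"] is not None:
        anchor_len = cons.five_prime_anchor[1]
        if seg["hit5"].query_end >= anchor_len - 3 and (seg["sine_r_cons_interval"][0] or 0) <= 3:
            vntr_length = vntr_iv[1] - vntr_iv[0]
    polya_call = seg["polya"]
    body_end = seg["hit3"].target_end if seg["hit3"] is not None else (
        polya_call.start if polya_call else len(record.sequence)
    )
    return StructureAnnotation(
        insertion_id=record.id,
        subfamily=subfamily,
        evidence=evidence,
        regions=seg["regions"],
        full_length=full,
        truncation=trunc,
        truncation_offset_3prime=offset3,
        hotspot=hotspot,
        cryptic_signal=cryptic if hotspot != "none" else "none",
        cryptic_signal_found=cryptic_found,
        cryptic_marker=marker,
        hexamer_unit=seg["hexamer_unit"],
        hexamer_length=(hex_iv[1] - hex_iv[0]) if hex_iv else 0,
        mast2_bp=seg["mast2_bp"],
        vntr_length=vntr_length,
        polya_length=polya_call.length if polya_call else 0,
        polya_substitutions=polya_call.substitutions if polya_call else 0,
        body_interval=(seg["body_start"] or 0, body_end),
    )


def annotate_structures(
    records: list[InsertionRecord],
    consensuses: dict[str, SubfamilyConsensus],
    curation_results: list[CurationResult] | None = None,
    td_context: dict[str, str] | None = None,
    params: StructureParams = StructureParams(),
) -> list[StructureAnnotation]:
    by_id = {c.insertion_id: c for c in curation_results or []}
    return [
        annotate_structure(r, consensuses, by_id.get(r.id), td_context, params)
        for r in records
    ]


# ---------------------------------------------------------------------------
# cohort-level tables


def mine_hexamer_patterns(
    annotations: list[StructureAnnotation],
    min_share: int = 5,
    max_period: int = 25,
) -> pd.DataFrame:
    """Hexamer-region repeat units shared by >= *min_share* elements.

    Each region is decomposed into its minimal repeating unit via the
    prefix-function period; composite units longer than 6 bp are reported
    as-is when the region is a tandem of that longer unit.
    """
    per_pattern: dict[str, list[int]] = {}
    for ann in annotations:
        if ann.hexamer_unit is None or ann.hexamer_length == 0:
            continue
        region_iv = ann.regions.get("hexamer")
        if region_iv is None:
            continue
        unit = ann.hexamer_unit
        p = minimal_period(unit)
        if p < len(unit) and len(unit) % p == 0:
            unit = unit[:p]
        if len(unit) > max_period:
            continue
        copies = ann.hexamer_length // len(unit)
        per_pattern.setdefault(unit, []).append(copies)
    rows = [
        {
            "pattern": unit,
            "unit_length": len(unit),
            "n_elements": len(counts),
            "mean_copies": float(np.mean(counts)),
            "total_copies": int(np.sum(counts)),
        }
        for unit, counts in per_pattern.items()
        if len(counts) >= min_share
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["n_elements", "pattern"], ascending=[False, True])
        .reset_index(drop=True)
        if rows
        else pd.DataFrame(
            columns=["pattern", "unit_length", "n_elements", "mean_copies", "total_copies"]
        )
    )


def summarize_regions(annotations: list[StructureAnnotation]) -> pd.DataFrame:
    """Per-subfamily hexamer/VNTR/poly-A metrics and truncation breakdown.

    VNTR statistics include only elements whose VNTR is complete (not
    truncated within the region).
    """
    rows = []
    anns = [a for a in annotations if a.subfamily not in (UNCLASSIFIABLE,)]
    for subfamily in sorted({a.subfamily for a in anns}):
        group = [a for a in anns if a.subfamily == subfamily]
        hexl = [a.hexamer_length for a in group if a.hexamer_length > 0]
        vntr = [a.vntr_length for a in group if a.vntr_length is not None]
        polya = [a.polya_length for a in group if a.polya_length > 0]
        def _stats(vals):
            if not vals:
                return {"mean": np.nan, "median": np.nan, "min": np.nan, "max": np.nan}
            return {
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
        row = {"subfamily": subfamily, "n": len(group)}
        for prefix, vals in (("hexamer", hexl), ("vntr", vntr), ("polya", polya)):
            for key, val in _stats(vals).items():
                row[f"{prefix}_{key}"] = val
        row["full_length_fraction"] = float(np.mean([a.full_length for a in group]))
        for t in ("none", "5p", "3p", "both"):
            row[f"trunc_{t}"] = sum(a.truncation == t for a in group)
        rows.append(row)
    return pd.DataFrame(rows)
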