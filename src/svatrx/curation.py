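"""Callset curation: TSD, poly-A and endonuclease-site detection plus the
reference-absence check.

A retrotransposition event inserted by target-primed reverse transcription
leaves a short target-site duplication (TSD) flanking the new element and a
3' poly-A tail.  Curation confirms these hallmarks for every putative
insertion and verifies that the inserted sequence is genuinely absent from
the reference at the insertion site, rejecting reference-present artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .align import ReferenceIndex, ScoringParams, align_local
from .model import InsertionRecord

logger = logging.getLogger(__name__)

EN_CONSENSUS = "TTAAAA"  # L1 endonuclease bottom-strand nick consensus TT|AAAA


@dataclass(frozen=True)
class CurationParams:
    tsd_min_len: int = 5
    tsd_max_len: int = 30
    tsd_max_mismatch_fraction: float = 0.1
    polya_min_len: int = 8
    polya_min_a_fraction: float = 0.8
    ref_absent_min_identity: float = 0.95
    ref_absent_min_cover: float = 0.5
    ref_neighborhood: int = 1000
    scoring: ScoringParams = ScoringParams()


@dataclass
class TsdCall:
    sequence: str
    length: int
    mismatches: int


@dataclass
class PolyACall:
    start: int  # on the insertion sequence
    end: int
    length: int
    substitutions: int
    signal_found: bool
    signal_start: int | None = None


@dataclass
class CurationResult:
    insertion_id: str
    tsd: TsdCall | None
    polya: PolyACall | None
    en_site_score: float
    reference_absent: bool
    verdict: bool
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.verdict and not self.failure_reasons:
            raise ValueError("failed curation must carry failure reasons")


# ---------------------------------------------------------------------------
# poly-A run helpers (shared with the synthetic-data generator)


def a_run_backward(seq: str, end: int, min_frac: float = 0.8) -> tuple[int, int]:
    """Maximal A-run ending at *end*, walking left.

    Isolated non-A substitutions are absorbed; two consecutive non-A bases
    terminate the run.  The window is then trimmed from its far (left) end
    until the overall A-fraction reaches *min_frac*.  Returns
    (start, substitutions).
    """
    i = end - 1
    while i >= 0:
        if seq[i] == "A" or (i - 1 >= 0 and seq[i - 1] == "A"):
            i -= 1
            continue
        break
    start = i + 1
    # trim: start on an A, and drop leading stretches until the overall
    # fraction is acceptable
    while start < end:
        while start < end and seq[start] != "A":
            start += 1
        window = seq[start:end]
        if not window:
            break
        subs = sum(1 for c in window if c != "A")
        if (len(window) - subs) / len(window) >= min_frac:
            break
        first_sub = next(k for k, c in enumerate(window) if c != "A")
        start += first_sub + 1
    subs = sum(1 for c in seq[start:end] if c != "A")
    return start, subs


def a_run_forward(seq: str, start: int, min_frac: float = 0.8) -> tuple[int, int]:
    """Maximal A-run starting at *start*, walking right (mirror of backward)."""
    n = len(seq)
    i = start
    while i < n:
        if seq[i] == "A" or (i + 1 < n and seq[i + 1] == "A"):
            i += 1
            continue
        break
    end = i
    while end > start:
        while end > start and seq[end - 1] != "A":
            end -= 1
        window = seq[start:end]
        if not window:
            break
        subs = sum(1 for c in window if c != "A")
        if (len(window) - subs) / len(window) >= min_frac:
            break
        last_sub = max(k for k, c in enumerate(window) if c != "A")
        end = start + last_sub
    subs = sum(1 for c in seq[start:end] if c != "A")
    return end, subs


# ---------------------------------------------------------------------------
# operations


def detect_tsd(record: InsertionRecord, params: CurationParams = CurationParams()) -> TsdCall | None:
    """Longest suffix of the left flank matching a prefix of the right flank.

    Candidates allow up to ``tsd_max_mismatch_fraction`` mismatches; ties
    break toward the longer candidate, then fewer mismatches (the scan is
    longest-first, so the first acceptable length wins).
    """
    left, right = record.left_flank, record.right_flank
    max_len = min(params.tsd_max_len, len(left), len(right))
    for length in range(max_len, params.tsd_min_len - 1, -1):
        lseq = left[-length:]
        rseq = right[:length]
        allowed = int(params.tsd_max_mismatch_fraction * length)
        mismatches = 0
        for a, b in zip(lseq, rseq):
            if a != b or a == "N":
                mismatches += 1
                if mismatches > allowed:
                    break
        if mismatches <= allowed:
            return TsdCall(sequence=lseq, length=length, mismatches=mismatches)
    return None


def detect_polya(
    record: InsertionRecord,
    tsd: TsdCall | None = None,
    params: CurationParams = CurationParams(),
) -> PolyACall | None:
    """Locate the terminal poly-A tail of the insertion.

    The tail ends at the last base before the 3' TSD, i.e. at the end of the
    insertion sequence.  When a terminal AATAAA polyadenylation signal is
    present the tail is counted downstream of it; otherwise a maximal A-run
    is walked back from the 3' end.
    """
    seq = record.sequence
    end = len(seq)
    start, subs = a_run_backward(seq, end, params.polya_min_a_fraction)
    # a terminal AATAAA overlapping the walked window belongs to the signal,
    # not the tail: the tail is counted downstream of it
    sig = seq.rfind("AATAAA", 0, end)
    found = False
    sig_start: int | None = None
    if sig >= 0 and sig + 6 >= start:
        start = sig + 6
        while start < end and seq[start] != "A":
            start += 1
        subs = sum(1 for c in seq[start:end] if c != "A")
        found = True
        sig_start = sig
    elif sig >= 0 and start - (sig + 6) <= 10:
        found = True
        sig_start = sig
    length = end - start
    if length < params.polya_min_len:
        return None
    if (length - subs) / length < params.polya_min_a_fraction:
        return None
    return PolyACall(
        start=start,
        end=end,
        length=length,
        substitutions=subs,
        signal_found=found,
        signal_start=sig_start,
    )


def score_en_site(
    record: InsertionRecord, tsd: TsdCall, params: CurationParams = CurationParams()
) -> float:
    """Match score of the 6 bp spanning the bottom-strand nick against TT|AAAA.

    The L1 endonuclease nicks between TT and AAAA; with the TSD beginning at
    the first A, the scored window is the last two flank bases before the
    TSD plus the TSD's first four bases.  Returns the fraction of matching
    positions (1.0 for a perfect TTAAAA).
    """
    left = record.left_flank
    i = len(left) - tsd.length
    if i < 2 or tsd.length < 4:
        warnings.warn(f"{record.id}: flank too short to window the EN site; score 0")
        return 0.0
    window = left[i - 2 : i + 4]
    return sum(1 for a, b in zip(window, EN_CONSENSUS) if a == b) / len(EN_CONSENSUS)


def check_reference_absent(
    record: InsertionRecord,
    reference: ReferenceIndex,
    params: CurationParams = CurationParams(),
) -> bool:
    """True iff the insertion body is absent from the reference around the site.

    The body is aligned locally against +/- ``ref_neighborhood`` bp of the
    insertion point; the record counts as reference-present when a hit with
    identity >= 0.95 covers at least half of the body.
    """
    if record.chrom not in reference.sequences:
        warnings.warn(f"{record.id}: chromosome {record.chrom!r} not in reference")
        return True
    chrom_seq = reference.sequences[record.chrom]
    p0 = record.pos  # 1-based point == 0-based index of the first base right of it
    lo = max(0, p0 - params.ref_neighborhood)
    hi = min(len(chrom_seq), p0 + params.ref_neighborhood)
    window = chrom_seq[lo:hi]
    body = record.sequence
    floor = 0.25 * len(body) * params.scoring.match
    hits = align_local(body, window, params.scoring, score_floor=floor, max_hits=5)
    for hit in hits:
        cover = (hit.query_end - hit.query_start) / len(body)
        if hit.identity >= params.ref_absent_min_identity and cover >= params.ref_absent_min_cover:
            return False
    return True


def curate_callset(
    records: list[InsertionRecord],
    reference: ReferenceIndex | dict[str, str],
    params: CurationParams = CurationParams(),
) -> list[CurationResult]:
    """Assign a pass/fail verdict with machine-readable reasons to each record.

    Pass requires a TSD of at least the configured minimum length, a poly-A
    tail of >= 8 bp and absence of the inserted sequence from the reference.
    The endonuclease-site score is advisory (logged, never a filter).
    """
    if not records:
        return []
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(dict(reference))
    results: list[CurationResult] = []
    for record in records:
        reasons: list[str] = []
        tsd = polya = None
        en_score = 0.0
        try:
            tsd = detect_tsd(record, params)
            if tsd is None:
                reasons.append("no_tsd")
            else:
                en_score = score_en_site(record, tsd, params)
            polya = detect_polya(record, tsd, params)
            if polya is None:
                reasons.append("no_polya")
            absent = check_reference_absent(record, reference, params)
            if not absent:
                reasons.append("reference_present")
        except Exception as exc:  # malformed record: fail, never raise
            reasons.append(f"error:{type(exc).__name__}")
            absent = False
        results.append(
            CurationResult(
                insertion_id=record.id,
                tsd=tsd,
                polya=polya,
                en_site_score=en_score,
                reference_absent=absent,
                verdict=not reasons,
                failure_reasons=reasons,
            )
        )
    n_pass = sum(r.verdict for r in results)
    logger.info("curation: %d/%d records pass", n_pass, len(results))
    return results
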