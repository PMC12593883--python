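"""Pairwise alignment primitives used throughout the pipeline.

Two operations are exposed:

``align_semiglobal``
    Affine-gap alignment in which the query must be aligned end to end while
    overhangs of the target are free ("glocal").  Used to compare an element
    against a subfamily consensus.

``align_local``
    Smith-Waterman-style local alignment of a query against one or more
    target sequences, returning every non-overlapping hit above a score
    floor.  Large targets are pre-screened with exact k-mer seeds so that
    tracing a transduced cargo across a full reference stays fast; small
    targets are scanned exhaustively.

Scoring uses an affine gap model where a gap of length L costs
``gap_open + L * gap_extend``.  ``N`` bases never score as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .model import check_dna

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "ReferenceIndex",
    "align_semiglobal",
    "align_local",
]


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring configuration (defaults tuned for >90%-identity DNA)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0  # cost of opening a gap, excluding the first base
    gap_extend: float = -1.0

    def substitution_matrix(self) -> substitution_matrices.Array:
        mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
        for a in "ACGTN":
            for b in "ACGTN":
                mat[a, b] = self.match if (a == b and a != "N") else self.mismatch
        return mat


DEFAULT_SCORING = ScoringParams()


@dataclass
class AlignmentResult:
    """One pairwise alignment between a query and a (named) target sequence.

    ``ops`` is a CIGAR-like list of ``(op, length)`` with ``M`` consuming both
    sequences, ``I`` consuming only the query and ``D`` only the target; it
    covers exactly the core alignment between ``query_interval`` and
    ``target_interval`` (end gaps excluded).  ``identity`` is
    matches / aligned columns over that core.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float
    score: float
    ops: list[tuple[str, int]] = field(default_factory=list)
    target_name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0 + 1e-9:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        qlen = sum(n for op, n in self.ops if op in "MI")
        tlen = sum(n for op, n in self.ops if op in "MD")
        if qlen != self.query_end - self.query_start:
            raise ValueError("ops inconsistent with query interval")
        if tlen != self.target_end - self.target_start:
            raise ValueError("ops inconsistent with target interval")

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / max(1, self._query_len)

    _query_len: int = 0  # set by the constructors below

    def map_query_to_target(self, qpos: int) -> int:
        """Project a query coordinate onto the target through the alignment.

        Positions outside the aligned core are clamped to its ends; positions
        falling inside a target gap map to the gap's left edge.
        """
        if qpos <= self.query_start:
            return self.target_start
        if qpos >= self.query_end:
            return self.target_end
        q, t = self.query_start, self.target_start
        for op, n in self.ops:
            if op == "M":
                if qpos < q + n:
                    return t + (qpos - q)
                q += n
                t += n
            elif op == "I":
                if qpos < q + n:
                    return t
                q += n
            else:  # D
                t += n
        return self.target_end

    def map_target_to_query(self, tpos: int) -> int:
        if tpos <= self.target_start:
            return self.query_start
        if tpos >= self.target_end:
            return self.query_end
        q, t = self.query_start, self.target_start
        for op, n in self.ops:
            if op == "M":
                if tpos < t + n:
                    return q + (tpos - t)
                q += n
                t += n
            elif op == "I":
                q += n
            else:  # D
                if tpos < t + n:
                    return q
                t += n
        return self.query_end


def _make_aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = params.substitution_matrix()
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    if mode == "global":
        # free end gaps for the target: the query aligns end to end inside it
        aligner.end_deletion_score = 0.0
    return aligner


def _result_from_alignment(
    aln: Align.Alignment,
    query: str,
    target: str,
    score: float,
    target_name: str = "",
    target_offset: int = 0,
) -> AlignmentResult | None:
    tblocks, qblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    ops: list[tuple[str, int]] = []
    matches = 0
    columns = 0
    prev_q = prev_t = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_q is not None:
            if qs > prev_q:
                ops.append(("I", int(qs - prev_q)))
                columns += qs - prev_q
            if ts > prev_t:
                ops.append(("D", int(ts - prev_t)))
                columns += ts - prev_t
        n = int(qe - qs)
        ops.append(("M", n))
        columns += n
        qseg = query[qs:qe]
        tseg = target[ts:te]
        matches += sum(1 for a, b in zip(qseg, tseg) if a == b and a != "N")
        prev_q, prev_t = qe, te
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    # merge adjacent same-op runs left by zip bookkeeping
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    res = AlignmentResult(
        query_start=q0,
        query_end=q1,
        target_start=t0 + target_offset,
        target_end=t1 + target_offset,
        identity=matches / columns if columns else 0.0,
        score=float(score),
        ops=merged,
        target_name=target_name,
    )
    res._query_len = len(query)
    return res


def align_semiglobal(
    query: str, target: str, params: ScoringParams = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal affine-gap alignment of the full query within the target.

    End gaps of the target are free; identity is computed over the aligned
    core only (end gaps excluded).  Deterministic for fixed parameters.
    """
    check_dna(query, "query")
    check_dna(target, "target")
    aligner = _make_aligner(params, "global")
    alignments = aligner.align(target, query)
    aln = alignments[0]
    res = _result_from_alignment(aln, query, target, alignments.score)
    if res is None:  # degenerate: nothing aligned (all-gap optimum)
        res = AlignmentResult(0, 0, 0, 0, 0.0, float(alignments.score))
        res._query_len = len(query)
    return res


def semiglobal_score(
    query: str, target: str, params: ScoringParams = DEFAULT_SCORING
) -> float:
    """Score-only semi-global alignment (much faster than a full traceback)."""
    check_dna(query, "query")
    check_dna(target, "target")
    return float(_make_aligner(params, "global").score(target, query))


class ReferenceIndex:
    """A set of named target sequences with an exact k-mer seed index.

    The index is built lazily on first large-target query and lets
    :func:`align_local` restrict dynamic programming to seeded windows.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 13) -> None:
        if not sequences:
            raise ValueError("empty reference")
        self.sequences = {name: check_dna(seq, name) for name, seq in sequences.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] | None = None

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def _build(self) -> None:
        index: dict[str, list[tuple[str, int]]] = {}
        k = self.k
        for name in sorted(self.sequences):
            seq = self.sequences[name]
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((name, i))
        self._index = index

    def seed_hits(self, query: str) -> dict[str, list[int]]:
        """Target positions (per sequence) sharing any exact query k-mer."""
        if self._index is None:
            self._build()
        assert self._index is not None
        k = self.k
        hits: dict[str, list[int]] = {}
        for i in range(0, max(1, len(query) - k + 1)):
            for name, pos in self._index.get(query[i : i + k], ()):
                hits.setdefault(name, []).append(pos - i)
        return hits


Target = Union[str, Mapping[str, str], ReferenceIndex]

# below this many DP cells the target is scanned exhaustively, no seeding
_EXHAUSTIVE_CELLS = 2_000_000


def _coerce_target(target: Target) -> ReferenceIndex:
    if isinstance(target, ReferenceIndex):
        return target
    if isinstance(target, str):
        return ReferenceIndex({"": target})
    return ReferenceIndex(dict(target))


def _windows_from_seeds(
    starts: list[int], qlen: int, seqlen: int, pad: int = 50
) -> list[tuple[int, int]]:
    starts = sorted(starts)
    windows: list[tuple[int, int]] = []
    lo = hi = None
    for s in starts:
        if lo is None:
            lo, hi = s, s
        elif s - hi <= qlen + pad:
            hi = s
        else:
            windows.append((max(0, lo - pad), min(seqlen, hi + qlen + pad)))
            lo, hi = s, s
    if lo is not None:
        windows.append((max(0, lo - pad), min(seqlen, hi + qlen + pad)))
    # merge any overlap introduced by padding
    merged: list[tuple[int, int]] = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


def _scan_segment(
    aligner: Align.PairwiseAligner,
    query: str,
    seq: str,
    offset: int,
    name: str,
    floor: float,
    out: list[AlignmentResult],
    max_hits: int,
) -> None:
    if len(seq) < 4 or len(out) >= max_hits:
        return
    alignments = aligner.align(seq, query)
    if alignments.score < floor:
        return
    res = _result_from_alignment(
        alignments[0], query, seq, alignments.score, target_name=name, target_offset=offset
    )
    if res is None:
        return
    out.append(res)
    left_end = res.target_start - offset
    right_start = res.target_end - offset
    _scan_segment(aligner, query, seq[:left_end], offset, name, floor, out, max_hits)
    _scan_segment(
        aligner, query, seq[right_start:], offset + right_start, name, floor, out, max_hits
    )


def align_local(
    query: str,
    target: Target,
    params: ScoringParams = DEFAULT_SCORING,
    score_floor: float | None = None,
    max_hits: int = 50,
) -> list[AlignmentResult]:
    """All non-overlapping local alignments with score >= the floor.

    Hits are sorted by score descending, ties broken by (target id,
    position).  The top hit carries the optimal Smith-Waterman score for the
    pair.  The default floor is ``min(len(query), 20)`` match-equivalents.
    """
    check_dna(query, "query")
    index = _coerce_target(target)
    floor = score_floor if score_floor is not None else min(len(query), 20) * params.match
    floor = max(floor, 1.0)
    aligner = _make_aligner(params, "local")
    hits: list[AlignmentResult] = []
    qlen = len(query)
    for name in sorted(index.sequences):
        seq = index.sequences[name]
        if qlen * len(seq) <= _EXHAUSTIVE_CELLS or qlen < index.k:
            _scan_segment(aligner, query, seq, 0, name, floor, hits, max_hits)
    big_names = [
        name
        for name in sorted(index.sequences)
        if qlen * len(index.sequences[name]) > _EXHAUSTIVE_CELLS and qlen >= index.k
    ]
    if big_names:
        seeds = index.seed_hits(query)
        for name in big_names:
            seq = index.sequences[name]
            for lo, hi in _windows_from_seeds(seeds.get(name, []), qlen, len(seq)):
                _scan_segment(aligner, query, seq[lo:hi], lo, name, floor, hits, max_hits)
    hits.sort(key=lambda r: (-r.score, r.target_name, r.target_start))
    for h in hits:
        h._query_len = qlen
    return hits
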