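"""Tandem-repeat primitives (minimal period, unit decomposition)."""

from __future__ import annotations


def prefix_function(s: str) -> list[int]:
    pi = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi


def minimal_period(s: str) -> int:
    """Smallest p with s[i] == s[i-p] for all i >= p (partial last unit allowed)."""
    if not s:
        return 0
    pi = prefix_function(s)
    return len(s) - pi[-1]


def decompose_tandem(s: str) -> tuple[str, int, int]:
    """Decompose into (unit, full copies, trailing partial length)."""
    if not s:
        return "", 0, 0
    p = minimal_period(s)
    return s[:p], len(s) // p, len(s) % p


def count_unit_copies_backward(seq: str, end: int, unit: str, lower: int = 0) -> int:
    """Number of consecutive exact copies of *unit* ending at *end*."""
    p = len(unit)
    if p == 0:
        return 0
    n = 0
    i = end
    while i - p >= lower and seq[i - p : i] == unit:
        n += 1
        i -= p
    return n
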