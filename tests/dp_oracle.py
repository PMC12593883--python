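"""Independent full-dynamic-programming alignment oracles for the tests.

Brute-force Gotoh implementations (three-matrix affine gaps) kept separate
from the package's alignment path.  Conventions match the package: a gap of
length L costs open + L*extend, and N never scores as a match.
"""

from __future__ import annotations

import numpy as np

NEG = -1e9


def _s(a: str, b: str, match: float, mismatch: float) -> float:
    return match if (a == b and a != "N") else mismatch


def semiglobal_score_oracle(
    q: str, t: str, match=1.0, mismatch=-1.0, open_=4.0, ext=1.0
) -> float:
    """Optimal score aligning the full query inside the target (free target
    overhangs)."""
    n, m = len(q), len(t)
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, :] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = -(open_ + i * ext)
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_ - ext, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_ - ext, F[i - 1, j] - ext)
            H[i, j] = max(
                H[i - 1, j - 1] + _s(q[i - 1], t[j - 1], match, mismatch), E[i, j], F[i, j]
            )
    return float(H[n, :].max())


def local_score_oracle(q: str, t: str, match=1.0, mismatch=-1.0, open_=4.0, ext=1.0) -> float:
    """Optimal Smith-Waterman local score with affine gaps."""
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_ - ext, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_ - ext, F[i - 1, j] - ext)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + _s(q[i - 1], t[j - 1], match, mismatch),
                E[i, j],
                F[i, j],
            )
            best = max(best, H[i, j])
    return float(best)


def brute_force_periods(s: str) -> int:
    """Smallest p such that s[i] == s[i-p] for all i >= p, by direct scan."""
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    return len(s)
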