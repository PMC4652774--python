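"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (direct scanning, exhaustive
enumeration, full dynamic programming) and shares no code with the
package's search path.
"""

from __future__ import annotations

import numpy as np


def naive_suffix_array(text: str) -> list[int]:
    """Rotation sort by direct string comparison (matches index convention)."""
    n = len(text)
    doubled = text + text
    return sorted(range(n), key=lambda i: (doubled[i : i + n], i))


def naive_count(text: str, pattern: str) -> int:
    return sum(1 for i in range(len(text) - len(pattern) + 1)
               if text[i : i + len(pattern)] == pattern)


def naive_positions(text: str, pattern: str) -> list[int]:
    return [i for i in range(len(text) - len(pattern) + 1)
            if text[i : i + len(pattern)] == pattern]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def all_w_hits_oracle(query: str, subject: str, w: int) -> set[tuple[int, int, str]]:
    """(q, s_plus, strand) of every exact w-window match, both strands."""
    hits = set()
    table: dict[str, list[tuple[str, int]]] = {}
    rc = revcomp(subject)
    L = len(subject)
    for i in range(L - w + 1):
        table.setdefault(subject[i : i + w], []).append(("+", i))
        table.setdefault(rc[i : i + w], []).append(("-", i))
    for qi in range(len(query) - w + 1):
        for strand, si in table.get(query[qi : qi + w], ()):
            hits.add((qi, si if strand == "+" else L - si - w, strand))
    return hits


def best_segment_through_seed(scores: np.ndarray, seed_start: int, seed_end: int) -> int:
    """Max-sum contiguous segment containing [seed_start, seed_end)."""
    best = -(10 ** 9)
    n = len(scores)
    prefix = np.concatenate([[0], np.cumsum(scores)])
    for i in range(seed_start + 1):
        for j in range(seed_end, n + 1):
            v = prefix[j] - prefix[i]
            if v > best:
                best = int(v)
    return best


def smith_waterman_affine(a, b, reward, penalty, gap_open, gap_extend) -> int:
    """Full unbanded local alignment score; gap of g costs open + g*extend."""
    na, nb = len(a), len(b)
    NEG = float(-1e18)
    H = np.zeros((na + 1, nb + 1))
    Ix = np.full((na + 1, nb + 1), NEG)
    Iy = np.full((na + 1, nb + 1), NEG)
    best = 0.0
    for i in range(1, na + 1):
        sub_row = np.where(np.asarray(b) == a[i - 1], reward, penalty)
        for j in range(1, nb + 1):
            ix = max(H[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend)
            iy = max(H[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend)
            m = H[i - 1][j - 1] + sub_row[j - 1]
            Ix[i][j], Iy[i][j] = ix, iy
            H[i][j] = max(m, ix, iy, 0.0)
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def bisect_lambda(reward: int, penalty: int, p_match: float, iters: int = 200) -> float:
    """Positive root of p e^{lam*r} + (1-p) e^{lam*q} = 1 by bisection."""

    def f(lam):
        return (p_match * np.exp(lam * reward)
                + (1.0 - p_match) * np.exp(lam * penalty) - 1.0)

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
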