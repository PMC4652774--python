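"""Precomputed bi-intervals for every k-mer, attached to the index.

The table has exactly ``4**k`` entries addressed by the 2-bit k-mer code
(A=0, C=1, G=2, T=3, leftmost symbol most significant).  Present k-mers
carry the bi-interval that ``k`` successive backward extensions from the
empty interval would produce; absent or uncodable words map to the empty
interval.  Construction walks the 4-ary k-mer trie depth first, pruning
empty intervals, so its cost tracks the number of distinct k-mers in the
database rather than 4^k full searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fmd_index import BiInterval, EMPTY_BIINTERVAL, FMDIndex

MAX_K = 14


@dataclass
class KmerLookupTable:
    k: int
    lower: np.ndarray      # int64[4**k]
    lower_rc: np.ndarray   # int64[4**k]
    size: np.ndarray       # int64[4**k]

    def __post_init__(self):
        expected = 4 ** self.k
        if not (len(self.lower) == len(self.lower_rc) == len(self.size) == expected):
            raise ValueError(f"lookup table must have exactly 4^{self.k} entries")

    @property
    def n_present(self) -> int:
        return int(np.count_nonzero(self.size))

    def get(self, code: int | None) -> BiInterval:
        if code is None:
            return EMPTY_BIINTERVAL
        return BiInterval(
            int(self.lower[code]), int(self.lower_rc[code]), int(self.size[code])
        )


def kmer_code(word) -> int | None:
    """2-bit code of a k-mer; ``None`` if any symbol is ambiguous.

    Accepts a string over the nucleotide alphabet or an array of internal
    integer codes (1..4); ambiguity (``N`` etc., internal code 0) makes
    the word uncodable.
    """
    code = 0
    if isinstance(word, str):
        for ch in word:
            v = "ACGT".find(ch.upper())
            if v < 0:
                return None
            code = (code << 2) | v
        return code
    for a in word:
        if not 1 <= a <= 4:
            return None
        code = (code << 2) | (int(a) - 1)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range((k - 1) * 2, -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def build_lookup(index: FMDIndex, k: int, hard_mask: bool = False) -> KmerLookupTable:
    """Fill the 4^k table by pruned depth-first backward extension.

    ``hard_mask=True`` additionally zeroes entries of k-mers whose every
    database occurrence lies fully inside a soft-masked span, so such
    words can never seed a search.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_K:
        raise ValueError(
            f"k={k} would need {3 * 8 * 4 ** k / 2 ** 20:.0f} MiB of table; "
            f"maximum supported k is {MAX_K}"
        )
    n_entries = 4 ** k
    lower = np.zeros(n_entries, dtype=np.int64)
    lower_rc = np.zeros(n_entries, dtype=np.int64)
    size = np.zeros(n_entries, dtype=np.int64)
    # DFS over patterns grown by prepending symbols: a pattern of length d
    # with partial code c (of its d symbols) becomes a*4^d + c when symbol
    # a is prepended.
    stack = [(0, 0, index.empty_interval())]
    pow4 = [4 ** d for d in range(k + 1)]
    while stack:
        depth, code, bi = stack.pop()
        if depth == k:
            lower[code] = bi.lower
            lower_rc[code] = bi.lower_rc
            size[code] = bi.size
            continue
        for a in (1, 2, 3, 4):
            child = index.backward_ext(bi, a)
            if child.size:
                stack.append((depth + 1, (a - 1) * pow4[depth] + code, child))
    table = KmerLookupTable(k=k, lower=lower, lower_rc=lower_rc, size=size)
    if hard_mask:
        _apply_hard_mask(index, table)
    index.lookup_table = table
    return table


def _apply_hard_mask(index: FMDIndex, table: KmerLookupTable) -> None:
    k = table.k
    masked_by_subject: dict[str, list[tuple[int, int]]] = {}
    for sid, a, b in index.sequence_text.mask_intervals:
        masked_by_subject.setdefault(sid, []).append((a, b))
    if not masked_by_subject:
        return
    for code in np.nonzero(table.size)[0]:
        bi = table.get(int(code))
        all_masked = True
        for sid, off, strand in index.locate(bi):
            L = index.subject_length(sid)
            # plus-strand span of this occurrence
            if strand == "+":
                s, e = off, off + k
            else:
                s, e = L - off - k, L - off
            spans = masked_by_subject.get(sid, ())
            if not any(a <= s and e <= b for a, b in spans):
                all_masked = False
                break
        if all_masked:
            table.lower[code] = 0
            table.lower_rc[code] = 0
            table.size[code] = 0


def lookup(table: KmerLookupTable, word) -> BiInterval:
    """Constant-time fetch; empty interval for absent or uncodable words."""
    code = kmer_code(word)
    if code is not None and code >= 4 ** table.k:
        raise ValueError(f"word longer than table k={table.k}")
    return table.get(code)
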