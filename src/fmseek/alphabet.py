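"""Nucleotide alphabet used throughout the package.

The internal alphabet is ``{$, A, C, G, T}`` encoded as integers
``0..4`` with ``$ < A < C < G < T``.  ``$`` is a sentinel terminating
every sequence segment in the concatenated index text.  Ambiguous IUPAC
symbols never enter the index text (they are replaced at build time);
in queries they are encoded as 0 and treated as mismatching everything.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 0
A, C, G, T = 1, 2, 3, 4

ALPHABET_SIZE = 5

#: complement in integer code space; the sentinel is self-complementary.
COMP = np.array([0, 4, 3, 2, 1], dtype=np.uint8)

CODE_TO_CHAR = np.array(["$", "A", "C", "G", "T"])

CHAR_TO_CODE = {"A": A, "C": C, "G": G, "T": T, "$": SENTINEL, "U": T}

#: IUPAC ambiguity codes mapped to the set of nucleotide codes they stand for.
IUPAC_SETS = {
    "R": (A, G),
    "Y": (C, T),
    "S": (C, G),
    "W": (A, T),
    "K": (G, T),
    "M": (A, C),
    "B": (C, G, T),
    "D": (A, G, T),
    "H": (A, C, T),
    "V": (A, C, G),
    "N": (A, C, G, T),
}

IUPAC_CHARS = frozenset("ACGTU") | frozenset(IUPAC_SETS)


def is_iupac(ch: str) -> bool:
    return ch.upper() in IUPAC_CHARS


def encode_query(seq: str) -> np.ndarray:
    """Encode a query sequence; ambiguous symbols become 0 (match nothing).

    Raises ``ValueError`` for symbols outside the IUPAC nucleotide set.
    """
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        u = ch.upper()
        code = CHAR_TO_CODE.get(u)
        if code is not None and u != "$":
            out[i] = code
        elif u in IUPAC_SETS:
            out[i] = 0
        else:
            raise ValueError(f"non-IUPAC symbol {ch!r} at position {i}")
    return out


def decode(codes: np.ndarray) -> str:
    """Integer codes back to a string (sentinels render as ``$``)."""
    return "".join(CODE_TO_CHAR[np.asarray(codes)])


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (no sentinels expected)."""
    return COMP[np.asarray(codes)][::-1].copy()


def revcomp_str(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]
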