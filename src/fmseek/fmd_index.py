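"""Bidirectional BWT index over a database and its reverse complement.

The index text concatenates, for every database subject, the forward
segment and its reverse-complement segment, each terminated by a
sentinel.  On top of the suffix array of that text we keep the BWT, the
cumulative symbol counts ``C``, a checkpointed occurrence array and a
rank-sampled suffix array, which together support backward/forward
bi-interval extension and position lookup on both strands at once.

A *bi-interval* ``(lower, lower_rc, size)`` locates a pattern ``P``:
``[lower, lower + size)`` is the suffix-array interval of ``P`` and
``[lower_rc, lower_rc + size)`` the interval of its reverse complement.
Both intervals always have equal size because the text is closed under
reverse complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import CHAR_TO_CODE, COMP, IUPAC_SETS, SENTINEL, decode

PLUS = "+"
MINUS = "-"

_MAGIC = b"FMSEEKIDX\x01"
_FORMAT_VERSION = 2


class IndexFormatError(ValueError):
    """Raised when an index bundle is corrupt, truncated or incompatible."""


@dataclass(frozen=True)
class BiInterval:
    """Suffix-array bi-interval of a pattern and of its reverse complement."""

    lower: int
    lower_rc: int
    size: int

    @property
    def empty(self) -> bool:
        return self.size == 0


EMPTY_BIINTERVAL = BiInterval(0, 0, 0)


@dataclass(frozen=True)
class Segment:
    """One $-terminated stretch of the concatenated text."""

    subject_id: str
    strand: str           # PLUS or MINUS
    global_start: int     # offset of the first nucleotide in the text
    length: int           # nucleotides, excluding the sentinel


@dataclass
class SequenceText:
    """The concatenated index text plus the bookkeeping to interpret it."""

    text: np.ndarray                      # uint8 codes over {0..4}
    layout: list[Segment]
    ambiguity_log: list[tuple[str, int, str, str]]   # (subject, offset, original, replacement)
    mask_intervals: list[tuple[str, int, int]]       # (subject, start, end) half-open
    rng_seed: int

    @property
    def n(self) -> int:
        return int(len(self.text))

    def subject_length(self, subject_id: str) -> int:
        for seg in self.layout:
            if seg.subject_id == subject_id and seg.strand == PLUS:
                return seg.length
        raise KeyError(subject_id)


def build_text(
    subjects: Sequence[tuple],
    rng_seed: int = 0,
) -> SequenceText:
    """Assemble the bidirectional text from database subjects.

    ``subjects`` is a sequence of ``(id, sequence)`` or
    ``(id, sequence, mask_intervals)`` tuples.  Sequences may contain
    IUPAC ambiguity codes; each ambiguous position is replaced by a
    nucleotide drawn (seeded) from the code's possibility set and
    recorded in the ambiguity log.  Each subject segment is followed
    immediately by its reverse-complement segment, both $-terminated.
    """
    if not subjects:
        raise ValueError("database must contain at least one subject")
    rng = np.random.default_rng(rng_seed)
    parts: list[np.ndarray] = []
    layout: list[Segment] = []
    amb_log: list[tuple[str, int, str, str]] = []
    masks: list[tuple[str, int, int]] = []
    pos = 0
    for rec in subjects:
        if len(rec) == 2:
            sid, seq = rec
            mask: Iterable[tuple[int, int]] = ()
        else:
            sid, seq, mask = rec
        if not seq:
            raise ValueError(f"subject {sid!r} is empty")
        codes = np.zeros(len(seq), dtype=np.uint8)
        for i, ch in enumerate(seq):
            u = ch.upper()
            direct = CHAR_TO_CODE.get(u)
            if direct is not None and u != "$":
                codes[i] = direct
            elif u in IUPAC_SETS:
                choices = IUPAC_SETS[u]
                repl = int(choices[rng.integers(len(choices))])
                codes[i] = repl
                amb_log.append((sid, i, ch, decode([repl])))
            else:
                raise ValueError(
                    f"subject {sid!r}: symbol {ch!r} at position {i} "
                    "is not an IUPAC nucleotide code"
                )
        rc = COMP[codes][::-1]
        sent = np.array([SENTINEL], dtype=np.uint8)
        L = len(codes)
        layout.append(Segment(sid, PLUS, pos, L))
        parts.extend([codes, sent])
        pos += L + 1
        layout.append(Segment(sid, MINUS, pos, L))
        parts.extend([rc, sent])
        pos += L + 1
        for a, b in mask:
            if not (0 <= a <= b <= L):
                raise ValueError(f"subject {sid!r}: bad mask interval ({a}, {b})")
            masks.append((sid, int(a), int(b)))
    # One extra trailing sentinel makes every rotation of the text distinct
    # (no rotation can be periodic when '$$' occurs exactly once), which in
    # turn keeps the LF-mapping exact across the sentinel block.
    parts.append(np.array([SENTINEL], dtype=np.uint8))
    return SequenceText(
        text=np.concatenate(parts),
        layout=layout,
        ambiguity_log=amb_log,
        mask_intervals=masks,
        rng_seed=int(rng_seed),
    )


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by cyclic prefix doubling (numpy lexsort).

    Suffixes are compared as cyclic rotations: past a sentinel the
    comparison continues with the text start.  For patterns that never
    contain ``$`` (all search patterns here) the resulting intervals are
    identical to plain suffix order, and the rotation convention keeps
    the LF-mapping consistent across the sentinel block even when the
    text holds many ``$``-terminated segments.  Residual ties between
    fully periodic rotations (identical subjects) are broken by text
    position.  O(n log^2 n); adequate for the targeted database sizes.
    """
    n = len(text)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = text.astype(np.int64)
    idx = np.arange(n)
    k = 1
    while k < n:
        key2 = rank[(idx + k) % n]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order[0]] = 0
        bump = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank[order[1:]] = np.cumsum(bump)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2
    # fully periodic rotations remain tied; break by position
    return np.lexsort((idx, rank)).astype(np.int64)


class FMDIndex:
    """FM-index over the bidirectional text; see module docstring.

    Parameters mirror the build options: ``r`` is the suffix-array
    sampling interval (every r-th rank kept), ``occ_checkpoint`` the
    spacing of occurrence-array checkpoints with on-the-fly counting in
    between.
    """

    def __init__(
        self,
        text: SequenceText,
        r: int = 8,
        occ_checkpoint: int = 128,
        _sa: np.ndarray | None = None,
    ):
        if r < 1:
            raise ValueError("sampling interval r must be >= 1")
        if occ_checkpoint < 1:
            raise ValueError("occ checkpoint spacing must be >= 1")
        self.sequence_text = text
        self.r = int(r)
        self.occ_checkpoint = int(occ_checkpoint)
        t = text.text
        self.n = int(len(t))
        sa = suffix_array(t) if _sa is None else _sa
        # BWT: symbol preceding each suffix; the wrap at SA==0 lands on the
        # final sentinel, matching the B[i] = $ convention.
        self.bwt = t[(sa - 1) % self.n]
        counts = np.bincount(t, minlength=5).astype(np.int64)
        self.C = np.zeros(5, dtype=np.int64)
        self.C[1:] = np.cumsum(counts)[:-1]
        self._build_occ()
        self.sampled_sa = sa[:: self.r].copy()
        rank_of_zero = int(np.nonzero(sa == 0)[0][0])
        self._rank_of_text_start = rank_of_zero
        self._starts = np.array([s.global_start for s in text.layout], dtype=np.int64)

    # -- construction helpers -------------------------------------------------

    def _build_occ(self) -> None:
        cp = self.occ_checkpoint
        n = self.n
        n_ck = n // cp + 1
        ck = np.zeros((n_ck, 5), dtype=np.int64)
        onehot = np.zeros((n, 5), dtype=np.int64)
        onehot[np.arange(n), self.bwt] = 1
        csum = np.cumsum(onehot, axis=0)
        idx = np.arange(1, n_ck) * cp
        ck[1:] = csum[idx - 1]
        self._occ_ck = ck

    # -- primitives -----------------------------------------------------------

    def occ_all(self, i: int) -> np.ndarray:
        """Counts of each symbol in ``bwt[0:i]`` (exclusive prefix)."""
        cp = self.occ_checkpoint
        j = i // cp
        base = self._occ_ck[j]
        lo = j * cp
        if lo == i:
            return base
        return base + np.bincount(self.bwt[lo:i], minlength=5)

    def occ(self, a: int, i: int) -> int:
        """Occurrences of symbol ``a`` in ``bwt[0:i]``."""
        return int(self.occ_all(i)[a])

    def lf(self, i: int) -> int:
        """Last-to-first mapping: rank of the suffix starting one symbol earlier."""
        a = int(self.bwt[i])
        return int(self.C[a]) + self.occ(a, i)

    def empty_interval(self) -> BiInterval:
        return BiInterval(0, 0, self.n)

    def backward_ext(self, bi: BiInterval, a: int) -> BiInterval:
        """Bi-interval of ``aP`` given the bi-interval of ``P``."""
        a = int(a)
        if not 0 <= a <= 4:
            raise ValueError(f"symbol code {a} outside the {{$,A,C,G,T}} alphabet")
        if bi.size == 0:
            return EMPTY_BIINTERVAL
        lo = self.occ_all(bi.lower)
        hi = self.occ_all(bi.lower + bi.size)
        cnt = hi - lo
        new_lower = int(self.C[a]) + int(lo[a])
        new_size = int(cnt[a])
        if new_size == 0:
            return EMPTY_BIINTERVAL
        # The reverse-complement interval of P is subdivided by the symbol
        # following rc(P); sub-interval for comp(c) has size cnt[c], laid out
        # in ascending order of the following symbol: $, T->A, G->C, ...
        rc_order = (0, 4, 3, 2, 1)          # cnt index for following symbols $,A,C,G,T
        offset = 0
        comp_a = int(COMP[a])
        for follow_sym, cnt_idx in zip(range(5), rc_order):
            if follow_sym == comp_a:
                break
            offset += int(cnt[cnt_idx])
        return BiInterval(new_lower, bi.lower_rc + offset, new_size)

    def forward_ext(self, bi: BiInterval, a: int) -> BiInterval:
        """Bi-interval of ``Pa``: backward-extend the reverse complement."""
        swapped = BiInterval(bi.lower_rc, bi.lower, bi.size)
        out = self.backward_ext(swapped, int(COMP[int(a)]))
        if out.size == 0:
            return EMPTY_BIINTERVAL
        return BiInterval(out.lower_rc, out.lower, out.size)

    def search(self, pattern: np.ndarray | str) -> BiInterval:
        """Bi-interval of a pattern via repeated backward extension."""
        if isinstance(pattern, str):
            pattern = np.array([CHAR_TO_CODE[c.upper()] for c in pattern], dtype=np.uint8)
        bi = self.empty_interval()
        for a in pattern[::-1]:
            bi = self.backward_ext(bi, int(a))
            if bi.size == 0:
                return EMPTY_BIINTERVAL
        return bi

    def sa_lookup(self, k: int) -> int:
        """Suffix-array entry at rank ``k`` via the sampled SA and LF walk."""
        if not 0 <= k < self.n:
            raise IndexError(f"rank {k} out of range [0, {self.n})")
        it = 0
        while k % self.r != 0:
            if k == self._rank_of_text_start:
                return it
            k = self.lf(k)
            it += 1
        return int(self.sampled_sa[k // self.r]) + it

    # -- position mapping -----------------------------------------------------

    def locate(self, bi: BiInterval) -> list[tuple[str, int, str]]:
        """Map every rank of a bi-interval to ``(subject_id, offset, strand)``.

        Offsets are 0-based within the segment: for plus-strand hits this
        is the offset from the subject start; for minus-strand hits it is
        the offset within the reverse-complement segment.
        """
        out = []
        for rank in range(bi.lower, bi.lower + bi.size):
            pos = self.sa_lookup(rank)
            seg = self.segment_at(pos)
            out.append((seg.subject_id, pos - seg.global_start, seg.strand))
        return out

    def segment_at(self, pos: int) -> Segment:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        return self.sequence_text.layout[i]

    def segment_text(self, subject_id: str, strand: str) -> np.ndarray:
        """The nucleotide codes of one segment (no sentinel)."""
        for seg in self.sequence_text.layout:
            if seg.subject_id == subject_id and seg.strand == strand:
                t = self.sequence_text.text
                return t[seg.global_start : seg.global_start + seg.length]
        raise KeyError((subject_id, strand))

    def subject_length(self, subject_id: str) -> int:
        return self.sequence_text.subject_length(subject_id)

    @property
    def total_database_length(self) -> int:
        return sum(s.length for s in self.sequence_text.layout if s.strand == PLUS)

    # optional attached k-mer lookup table (set by lookup_table.build_lookup
    # or by load_index); kept here so one bundle round-trips both structures
    lookup_table = None


# -- persistence --------------------------------------------------------------


def _array_blob(arrays: dict[str, np.ndarray]) -> tuple[list[dict], bytes]:
    manifest = []
    chunks = []
    for name, arr in arrays.items():
        data = np.ascontiguousarray(arr).tobytes()
        manifest.append(
            {"name": name, "dtype": str(arr.dtype), "shape": list(arr.shape), "nbytes": len(data)}
        )
        chunks.append(data)
    return manifest, b"".join(chunks)


def save_index(index: FMDIndex, path) -> None:
    """Serialize an index (and its lookup table, if attached) to one file.

    The format is deliberately simple and deterministic: magic bytes, a
    JSON header, then raw little-endian array blobs in header order.
    """
    st = index.sequence_text
    arrays: dict[str, np.ndarray] = {
        "text": st.text,
        "bwt": index.bwt,
        "sampled_sa": index.sampled_sa,
    }
    header: dict = {
        "version": _FORMAT_VERSION,
        "r": index.r,
        "occ_checkpoint": index.occ_checkpoint,
        "n": index.n,
        "rng_seed": st.rng_seed,
        "layout": [
            [s.subject_id, s.strand, s.global_start, s.length] for s in st.layout
        ],
        "ambiguity_log": [list(e) for e in st.ambiguity_log],
        "mask_intervals": [list(m) for m in st.mask_intervals],
        "rank_of_text_start": index._rank_of_text_start,
        "lookup_k": None,
    }
    if index.lookup_table is not None:
        lt = index.lookup_table
        header["lookup_k"] = lt.k
        arrays["lt_lower"] = lt.lower
        arrays["lt_lower_rc"] = lt.lower_rc
        arrays["lt_size"] = lt.size
    manifest, blob = _array_blob(arrays)
    header["arrays"] = manifest
    hjson = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(hjson).to_bytes(8, "little"))
        fh.write(hjson)
        fh.write(blob)


def load_index(path) -> FMDIndex:
    """Load an index bundle written by :func:`save_index`."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError(f"{path}: not an fmseek index (bad magic bytes)")
        raw = fh.read(8)
        if len(raw) < 8:
            raise IndexFormatError(f"{path}: truncated header length")
        hlen = int.from_bytes(raw, "little")
        hjson = fh.read(hlen)
        if len(hjson) < hlen:
            raise IndexFormatError(f"{path}: truncated header")
        try:
            header = json.loads(hjson)
        except json.JSONDecodeError as exc:
            raise IndexFormatError(f"{path}: corrupt header ({exc})") from exc
        if header.get("version") != _FORMAT_VERSION:
            raise IndexFormatError(
                f"{path}: format version {header.get('version')} "
                f"(this build reads version {_FORMAT_VERSION})"
            )
        arrays = {}
        for ent in header["arrays"]:
            data = fh.read(ent["nbytes"])
            if len(data) < ent["nbytes"]:
                raise IndexFormatError(f"{path}: truncated array {ent['name']!r}")
            arrays[ent["name"]] = np.frombuffer(data, dtype=ent["dtype"]).reshape(
                ent["shape"]
            ).copy()
    layout = [Segment(sid, strand, int(gs), int(ln)) for sid, strand, gs, ln in header["layout"]]
    st = SequenceText(
        text=arrays["text"],
        layout=layout,
        ambiguity_log=[tuple(e) for e in header["ambiguity_log"]],
        mask_intervals=[tuple(m) for m in header["mask_intervals"]],
        rng_seed=int(header["rng_seed"]),
    )
    idx = FMDIndex.__new__(FMDIndex)
    idx.sequence_text = st
    idx.r = int(header["r"])
    idx.occ_checkpoint = int(header["occ_checkpoint"])
    idx.n = int(header["n"])
    idx.bwt = arrays["bwt"]
    counts = np.bincount(st.text, minlength=5).astype(np.int64)
    idx.C = np.zeros(5, dtype=np.int64)
    idx.C[1:] = np.cumsum(counts)[:-1]
    idx._build_occ()
    idx.sampled_sa = arrays["sampled_sa"]
    idx._starts = np.array([s.global_start for s in layout], dtype=np.int64)
    idx._rank_of_text_start = int(header["rank_of_text_start"])
    idx.lookup_table = None
    if header.get("lookup_k") is not None:
        from .lookup_table import KmerLookupTable

        idx.lookup_table = KmerLookupTable(
            k=int(header["lookup_k"]),
            lower=arrays["lt_lower"],
            lower_rc=arrays["lt_lower_rc"],
            size=arrays["lt_size"],
        )
    return idx


def build_index(
    text: SequenceText, r: int = 8, occ_checkpoint: int = 128
) -> FMDIndex:
    """Build the FMD-index of a :class:`SequenceText`."""
    return FMDIndex(text, r=r, occ_checkpoint=occ_checkpoint)
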