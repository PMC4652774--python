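"""Stride-based seed search: bi-interval identification and position detection.

The search scans the query at stride ``w - k + 1`` (the largest step that
cannot miss a w-length exact match), fetches the bi-interval of the k-mer
at each sampled position from the lookup table, and grows it by backward
extension toward the query start.  Every w-length query window anchored
at the sampled k-mer is completed by forward extension and emitted when
its bi-interval is non-empty, so the located seed set contains exactly
the pairs ``(q, s)`` where the query window of length ``w`` at ``q``
matches the database at ``s`` on either strand — nothing more, nothing
less.  Located intervals are then resolved to per-subject coordinates
through the sampled suffix array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import encode_query
from .fmd_index import BiInterval, FMDIndex, PLUS
from .lookup_table import KmerLookupTable, kmer_code


@dataclass(frozen=True)
class SeedingParams:
    """Seed search configuration; ``stride`` defaults to ``w - k + 1``.

    Strides above ``w - k + 1`` are permitted (useful for demonstrating
    that the default is the largest complete one) but forfeit the
    completeness guarantee.
    """

    w: int = 28
    k: int = 11
    stride: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.w < self.k:
            raise ValueError(f"seed length w={self.w} must be >= k={self.k}")
        if self.stride is None:
            object.__setattr__(self, "stride", self.w - self.k + 1)
        elif self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class SeedInterval:
    """A w-length query window together with the bi-interval of its matches."""

    query_id: str
    q_start: int
    length: int
    interval: BiInterval


@dataclass(frozen=True)
class Seed:
    """One exact w-length match between a query and a subject strand.

    ``s_offset`` is the plus-strand start of the matched subject window
    regardless of strand; minus-strand seeds match the reverse complement
    of ``subject[s_offset : s_offset + length]``.
    """

    query_id: str
    q_offset: int
    subject_id: str
    s_offset: int
    strand: str
    length: int


def mask_flags(length: int, mask_intervals) -> np.ndarray:
    flags = np.zeros(length, dtype=bool)
    for a, b in mask_intervals:
        flags[max(0, a) : min(length, b)] = True
    return flags


def find_seed_intervals(
    query,
    index: FMDIndex,
    table: KmerLookupTable,
    params: SeedingParams,
    query_id: str = "query",
    query_masks=(),
) -> list[SeedInterval]:
    """All w-length query windows with non-empty bi-intervals.

    ``query`` is a string or an array of internal codes (ambiguous = 0).
    Sampled positions whose k-mer lies entirely inside a soft-masked
    query span are skipped; ambiguous symbols terminate extension, acting
    as mismatches.  Queries shorter than ``w`` yield no intervals.
    """
    q = encode_query(query) if isinstance(query, str) else np.asarray(query)
    n = len(q)
    w, k, stride = params.w, params.k, params.stride
    if table.k != k:
        raise ValueError(f"lookup table built for k={table.k}, params ask k={k}")
    if n < w:
        return []
    masked = mask_flags(n, query_masks)
    emitted: dict[int, SeedInterval] = {}
    for i in range(0, n - k + 1, stride):
        if masked[i : i + k].all():
            continue
        base = table.get(kmer_code(q[i : i + k]))
        if base.size == 0:
            continue
        cur = base
        j = i
        lo = max(i + k - w, 0)
        while True:
            # cur is the bi-interval of q[j : i+k]
            if j <= n - w and j not in emitted:
                bi = cur
                t = i + k
                while t < j + w and bi.size:
                    a = int(q[t])
                    if a == 0:
                        bi = BiInterval(0, 0, 0)
                        break
                    bi = index.forward_ext(bi, a)
                    t += 1
                if bi.size:
                    emitted[j] = SeedInterval(query_id, j, w, bi)
            j -= 1
            if j < lo:
                break
            a = int(q[j])
            if a == 0:
                break
            cur = index.backward_ext(cur, a)
            if cur.size == 0:
                break
    return [emitted[j] for j in sorted(emitted)]


def resolve_seeds(index: FMDIndex, seed_intervals) -> list[Seed]:
    """Locate every rank of every interval and convert to subject coordinates.

    Minus-strand occurrences found at offset ``p`` of a reverse-complement
    segment of a length-``L`` subject are reported at plus-strand start
    ``L - p - w`` with strand '-'.  Duplicates are removed.
    """
    seen = set()
    seeds: list[Seed] = []
    for si in seed_intervals:
        w = si.length
        for sid, off, strand in index.locate(si.interval):
            if strand == PLUS:
                s_off = off
            else:
                s_off = index.subject_length(sid) - off - w
            key = (si.query_id, si.q_start, sid, strand, s_off)
            if key in seen:
                continue
            seen.add(key)
            seeds.append(Seed(si.query_id, si.q_start, sid, s_off, strand, w))
    return seeds


def diagonal(seed: Seed) -> int:
    """``s_offset - q_offset``; seeds sharing it are gap-free collinear."""
    return seed.s_offset - seed.q_offset


def sort_seeds(seeds) -> list[Seed]:
    """Deterministic extension order: diagonal-clustered, small offsets first."""
    return sorted(
        seeds,
        key=lambda s: (s.query_id, s.subject_id, s.strand, diagonal(s), s.s_offset),
    )
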