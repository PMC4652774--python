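"""Seed extension: diagonal filtering, ungapped and gapped X-drop alignment.

Seeds arrive sorted so that seeds on one diagonal cluster together with
smaller subject offsets first.  A per-diagonal tracker remembers the end
subject offset (*diagonal offset*) of the last ungapped alignment; a
later seed strictly inside that span is redundant and skipped.  Ungapped
alignments above a trigger score are refined by a banded affine-gap
X-drop dynamic program seeded at the anchor midpoint, and survivors are
scored with Karlin–Altschul statistics into E-values and bit scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .seeding import Seed, diagonal

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch/gap scores and extension/reporting cutoffs.

    Gap of length g costs ``gap_open + g * gap_extend``.  ``None`` cutoffs
    are resolved from the E-value cutoff (final score) and the trigger
    bit score (ungapped threshold) once search-space sizes are known.
    """

    reward: int = 1
    penalty: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    x_drop_ungapped: int = 20
    x_drop_gapped: int = 25
    ungapped_threshold: int | None = None
    min_score: int | None = None
    evalue_cutoff: float = 10.0
    trigger_bits: float = 25.0

    def __post_init__(self):
        if not (self.reward > 0 > self.penalty):
            raise ValueError("need reward > 0 > penalty")
        if self.x_drop_ungapped <= 0 or self.x_drop_gapped <= 0:
            raise ValueError("X-drop values must be positive")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be non-negative / positive")


@dataclass(frozen=True)
class UngappedAlignment:
    """Gap-free alignment identified by (q_start, s_start, length)."""

    q_start: int
    s_start: int
    length: int
    score: int

    @property
    def s_end(self) -> int:
        """End subject offset (inclusive) — the diagonal offset it produces."""
        return self.s_start + self.length - 1


@dataclass
class HSP:
    query_id: str
    subject_id: str
    strand: str
    q_start: int          # 0-based, half-open internally
    q_end: int
    s_start: int          # plus-strand subject coordinates, half-open
    s_end: int
    score: int
    num_identities: int
    num_mismatches: int
    num_gap_opens: int
    alignment_length: int
    evalue: float = math.inf
    bitscore: float = 0.0

    def identity_key(self):
        return (
            self.query_id, self.subject_id, self.strand,
            self.q_start, self.q_end, self.s_start, self.s_end,
            self.score, self.alignment_length,
        )


class SeedOrderError(ValueError):
    """Seeds reached the diagonal filter out of sort order."""


class DiagonalTracker:
    """Last diagonal offset per (query, subject, strand, diagonal)."""

    def __init__(self):
        self._D: dict[tuple, int] = {}
        self._last_seen: dict[tuple, int] = {}

    @staticmethod
    def key(seed: Seed) -> tuple:
        return (seed.query_id, seed.subject_id, seed.strand, diagonal(seed))

    def should_extend(self, seed: Seed) -> bool:
        key = self.key(seed)
        last = self._last_seen.get(key)
        if last is not None and seed.s_offset < last:
            raise SeedOrderError(
                f"seed at subject offset {seed.s_offset} after offset {last} "
                f"on diagonal {key[3]}"
            )
        self._last_seen[key] = seed.s_offset
        D = self._D.get(key)
        if D is None:
            return True
        return seed.s_offset >= D  # strictly smaller than D => redundant

    def update(self, seed: Seed, aln: UngappedAlignment) -> None:
        self._D[self.key(seed)] = aln.s_end


def ungapped_extend(
    query: np.ndarray, subject: np.ndarray, seed, scoring: ScoringParams
) -> UngappedAlignment:
    """Two-sided X-drop extension of an exact seed match.

    ``seed`` needs ``q_offset``, ``s_offset`` and ``length`` attributes;
    offsets are in the coordinate frame of ``subject`` (for minus-strand
    work pass the reverse-complement segment and frame offsets).
    Ambiguous query symbols (code 0) mismatch everything.
    """
    reward, penalty, xd = scoring.reward, scoring.penalty, scoring.x_drop_ungapped
    q0, s0, w = seed.q_offset, seed.s_offset, seed.length

    def side(qi, si, step):
        best = 0
        best_len = 0
        run = 0
        ln = 0
        while 0 <= qi < len(query) and 0 <= si < len(subject):
            run += reward if query[qi] == subject[si] and query[qi] != 0 else penalty
            ln += 1
            if run > best:
                best, best_len = run, ln
            if run <= best - xd:
                break
            qi += step
            si += step
        return best, best_len

    left_score, left_len = side(q0 - 1, s0 - 1, -1)
    right_score, right_len = side(q0 + w, s0 + w, +1)
    return UngappedAlignment(
        q_start=q0 - left_len,
        s_start=s0 - left_len,
        length=w + left_len + right_len,
        score=w * reward + left_score + right_score,
    )


# -- gapped X-drop DP ---------------------------------------------------------


def _xdrop_half(a: np.ndarray, b: np.ndarray, scoring: ScoringParams):
    """Extension alignment of prefixes of ``a`` against ``b`` with X-drop.

    Three-state affine DP starting at (0, 0); cells whose best score falls
    more than ``x_drop_gapped`` below the running maximum are pruned, which
    also bounds the band.  Returns ``(score, a_used, b_used, n_identity,
    n_mismatch, n_gap_open, n_gap_letters)`` for the best-scoring cell.
    """
    reward, penalty = scoring.reward, scoring.penalty
    go, ge, xd = scoring.gap_open, scoring.gap_extend, scoring.x_drop_gapped
    na, nb = len(a), len(b)
    M_STATE, IX, IY = 0, 1, 2
    # rows[i] maps j -> (M, Ix, Iy); back maps (i, j, state) -> predecessor state
    back: dict[tuple, int] = {}
    row0: dict[int, tuple] = {0: (0, NEG_INF, NEG_INF)}
    best_score, best_cell = 0, (0, 0, M_STATE)
    iy = -go
    for j in range(1, nb + 1):
        iy -= ge
        if iy <= best_score - xd:
            break
        row0[j] = (NEG_INF, NEG_INF, iy)
        back[(0, j, IY)] = M_STATE if j == 1 else IY
    prev = row0
    for i in range(1, na + 1):
        if not prev:
            break
        cur: dict[int, tuple] = {}
        ai = a[i - 1]
        jlo = min(prev)
        jhi = min(max(prev) + 1, nb)
        for j in range(jlo, jhi + 1):
            # match/mismatch from (i-1, j-1)
            m = NEG_INF
            pm = prev.get(j - 1)
            if pm is not None and j >= 1:
                base = max(pm)
                if base > NEG_INF:
                    m = base + (reward if (ai == b[j - 1] and ai != 0) else penalty)
                    back[(i, j, M_STATE)] = int(np.argmax(pm))
            # gap consuming a, from (i-1, j)
            ix = NEG_INF
            pv = prev.get(j)
            if pv is not None:
                opn = max(pv) - go - ge if max(pv) > NEG_INF else NEG_INF
                ext = pv[IX] - ge if pv[IX] > NEG_INF else NEG_INF
                if ext >= opn and ext > NEG_INF:
                    ix = ext
                    back[(i, j, IX)] = IX
                elif opn > NEG_INF:
                    ix = opn
                    back[(i, j, IX)] = int(np.argmax(pv))
            # gap consuming b, from (i, j-1)
            iy = NEG_INF
            ph = cur.get(j - 1)
            if ph is not None:
                opn = max(ph) - go - ge if max(ph) > NEG_INF else NEG_INF
                ext = ph[IY] - ge if ph[IY] > NEG_INF else NEG_INF
                if ext >= opn and ext > NEG_INF:
                    iy = ext
                    back[(i, j, IY)] = IY
                elif opn > NEG_INF:
                    iy = opn
                    back[(i, j, IY)] = int(np.argmax(ph))
            hbest = max(m, ix, iy)
            if hbest == NEG_INF or hbest <= best_score - xd:
                continue
            cur[j] = (m, ix, iy)
            if hbest > best_score:
                best_score = hbest
                best_cell = (i, j, int(np.argmax(cur[j])))
        prev = cur
    # traceback with event counting
    i, j, state = best_cell
    a_used, b_used = i, j
    n_id = n_mm = n_open = n_gap = 0
    while not (i == 0 and j == 0):
        prev_state = back[(i, j, state)]
        if state == M_STATE:
            if a[i - 1] == b[j - 1] and a[i - 1] != 0:
                n_id += 1
            else:
                n_mm += 1
            i -= 1
            j -= 1
        elif state == IX:
            n_gap += 1
            if prev_state != IX:
                n_open += 1
            i -= 1
        else:
            n_gap += 1
            if prev_state != IY:
                n_open += 1
            j -= 1
        state = prev_state
    return int(best_score), a_used, b_used, n_id, n_mm, n_open, n_gap


def gapped_extend(
    query: np.ndarray,
    subject: np.ndarray,
    anchor: UngappedAlignment,
    scoring: ScoringParams,
) -> HSP:
    """Gapped X-drop extension in both directions from the anchor midpoint.

    Coordinates in the returned record are in the frame of ``subject``;
    strand bookkeeping and E-values are added by the caller.
    """
    qm = anchor.q_start + anchor.length // 2
    sm = anchor.s_start + anchor.length // 2
    sr, ir, jr, idr, mmr, opr, gapr = _xdrop_half(query[qm:], subject[sm:], scoring)
    sl, il, jl, idl, mml, opl, gapl = _xdrop_half(
        query[:qm][::-1], subject[:sm][::-1], scoring
    )
    return HSP(
        query_id="", subject_id="", strand="+",
        q_start=qm - il, q_end=qm + ir,
        s_start=sm - jl, s_end=sm + jr,
        score=sl + sr,
        num_identities=idl + idr,
        num_mismatches=mml + mmr,
        num_gap_opens=opl + opr,
        alignment_length=idl + idr + mml + mmr + gapl + gapr,
    )


# -- Karlin–Altschul statistics ----------------------------------------------


def karlin_altschul_params(
    scoring: ScoringParams, background=(0.25, 0.25, 0.25, 0.25)
) -> tuple[float, float, float]:
    """Ungapped Karlin–Altschul ``(lambda, K, H)`` for match/mismatch scoring.

    ``lambda`` is the positive root of ``sum p_i p_j exp(lambda s_ij) = 1``;
    ``K`` follows the classic series expression evaluated by convolving the
    per-position score distribution; results are deterministic to 1e-6.
    """
    bg = np.asarray(background, dtype=float)
    if abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
        raise ValueError("background frequencies must be a distribution")
    p_match = float((bg ** 2).sum())
    probs = {scoring.reward: p_match, scoring.penalty: 1.0 - p_match}
    expected = sum(s * p for s, p in probs.items())
    if expected >= 0:
        raise ValueError(
            f"expected per-position score {expected:.4f} is non-negative; "
            "local alignment statistics are undefined for this scoring"
        )
    if max(probs) <= 0:
        raise ValueError("a positive score must be achievable")

    def f(lam):
        return sum(p * math.exp(lam * s) for s, p in probs.items()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-12, rtol=1e-14))

    d = math.gcd(*(abs(int(s)) for s in probs))  # score lattice span
    # tilted distribution and relative entropy H
    H = lam * sum(s * p * math.exp(lam * s) for s, p in probs.items())

    # sigma = sum_k (1/k) [ E(e^{lam S_k}; S_k < 0) + P(S_k >= 0) ]
    lo_s = min(probs)
    hi_s = max(probs)
    step = np.zeros(hi_s - lo_s + 1)
    for s, p in probs.items():
        step[s - lo_s] = p
    dist = np.array([1.0])
    d_lo = 0  # current distribution covers scores [d_lo, d_lo + len - 1]
    sigma = 0.0
    for kk in range(1, 400):
        dist = np.convolve(dist, step)
        d_lo += lo_s
        scores = d_lo + np.arange(len(dist))
        neg = scores < 0
        term = float((dist[neg] * np.exp(lam * scores[neg])).sum() + dist[~neg].sum())
        sigma += term / kk
        if term / kk < 1e-12:
            break
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


def evalue(score: float, lam: float, K: float, m_eff: float, n_eff: float) -> float:
    """``E = K m n exp(-lambda * score)``."""
    return K * m_eff * n_eff * math.exp(-lam * score)


def bitscore(score: float, lam: float, K: float) -> float:
    return (lam * score - math.log(K)) / math.log(2.0)


def raw_score_for_bits(bits: float, lam: float, K: float) -> int:
    return int(math.ceil((bits * math.log(2.0) + math.log(K)) / lam))


def raw_score_for_evalue(e: float, lam: float, K: float, m_eff: float, n_eff: float) -> int:
    return int(math.ceil(math.log(K * m_eff * n_eff / e) / lam))


# -- per-query pipeline -------------------------------------------------------


def _containment_filter(hsps: list[HSP]) -> list[HSP]:
    """Drop HSPs fully contained in a higher-scoring one on the same plane."""
    hsps = sorted(hsps, key=lambda h: (-h.score, h.s_start, h.q_start, h.s_end, h.q_end))
    kept: list[HSP] = []
    for h in hsps:
        contained = any(
            k.query_id == h.query_id
            and k.subject_id == h.subject_id
            and k.strand == h.strand
            and k.q_start <= h.q_start
            and h.q_end <= k.q_end
            and k.s_start <= h.s_start
            and h.s_end <= k.s_end
            and k.score >= h.score
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def extend_seeds(
    query: np.ndarray,
    index,
    seeds,
    scoring: ScoringParams,
    use_diagonal_filter: bool = True,
) -> list[HSP]:
    """Run sorted seeds through ungapped + gapped extension to final HSPs.

    Minus-strand seeds are extended against the reverse-complement segment
    (which the index text holds verbatim); their subject coordinates are
    mapped back to plus-strand convention in the returned records.
    """
    lam, K, _ = karlin_altschul_params(scoring)
    m_eff = len(query)
    n_eff = index.total_database_length
    trigger = scoring.ungapped_threshold
    if trigger is None:
        trigger = raw_score_for_bits(scoring.trigger_bits, lam, K)
    e_cut = scoring.evalue_cutoff
    min_score = scoring.min_score

    # work in the strand frame: seeds regrouped with frame subject offsets
    by_plane: dict[tuple, list] = {}
    for s in seeds:
        L = index.subject_length(s.subject_id)
        frame_off = s.s_offset if s.strand == "+" else L - s.s_offset - s.length
        fs = Seed(s.query_id, s.q_offset, s.subject_id, frame_off, s.strand, s.length)
        by_plane.setdefault((s.query_id, s.subject_id, s.strand), []).append(fs)

    final: list[HSP] = []
    for (qid, sid, strand), plane_seeds in sorted(by_plane.items()):
        subject = index.segment_text(sid, strand)
        L = index.subject_length(sid)
        tracker = DiagonalTracker()
        anchors: dict[tuple, UngappedAlignment] = {}
        from .seeding import sort_seeds

        for seed in sort_seeds(plane_seeds):
            if use_diagonal_filter:
                if not tracker.should_extend(seed):
                    continue
                aln = ungapped_extend(query, subject, seed, scoring)
                tracker.update(seed, aln)
            else:
                aln = ungapped_extend(query, subject, seed, scoring)
            anchors[(aln.q_start, aln.s_start, aln.length)] = aln
        plane_hsps: list[HSP] = []
        for aln in anchors.values():
            if aln.score < trigger:
                continue
            h = gapped_extend(query, subject, aln, scoring)
            h.query_id, h.subject_id, h.strand = qid, sid, strand
            if strand == "-":
                # frame coords -> plus-strand subject coords
                h.s_start, h.s_end = L - h.s_end, L - h.s_start
            h.evalue = evalue(h.score, lam, K, m_eff, n_eff)
            h.bitscore = bitscore(h.score, lam, K)
            if min_score is not None and h.score < min_score:
                continue
            if h.evalue > e_cut:
                continue
            plane_hsps.append(h)
        # exact duplicates first, then containment
        uniq = {}
        for h in plane_hsps:
            uniq.setdefault(h.identity_key(), h)
        final.extend(_containment_filter(list(uniq.values())))
    return final
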