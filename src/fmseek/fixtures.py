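"""Seeded synthetic databases, queries and adversarial constructions.

Everything a test needs is generated from one seeded generator, so the
same spec always produces byte-identical FASTA plus a machine-readable
truth manifest (JSON-lines) describing every planted feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .alphabet import revcomp_str

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters that fully determine a generated dataset."""

    seed: int = 0
    n_subjects: int = 3
    subject_length: tuple[int, int] = (2000, 5000)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_queries: int = 10
    query_length: tuple[int, int] = (100, 500)
    planted_fraction: float = 0.7
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    indel_length_p: float = 0.5       # geometric parameter for indel lengths
    ambiguity_rate: float = 0.0
    mask_span_rate: float = 0.0       # expected masked spans per kb of subject


def _random_seq(rng, length, composition) -> str:
    return "".join(rng.choice(BASES, size=length, p=list(composition)))


def gen_database(spec: FixtureSpec):
    """Random subjects with optional N runs and lowercase mask spans.

    Returns ``(records, manifest)`` where records are ``(id, seq)`` pairs
    (sequence case encodes soft-masking) and the manifest lists every
    injected feature.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    manifest = []
    lo, hi = spec.subject_length
    for i in range(spec.n_subjects):
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length, spec.base_composition))
        entry = {"type": "subject", "id": f"subj{i}", "length": length,
                 "n_runs": [], "mask_spans": []}
        if spec.ambiguity_rate > 0:
            n_runs = rng.poisson(spec.ambiguity_rate * length)
            for _ in range(n_runs):
                start = int(rng.integers(0, length))
                run = int(rng.integers(1, 6))
                for p in range(start, min(start + run, length)):
                    seq[p] = "N"
                entry["n_runs"].append([start, min(start + run, length)])
        if spec.mask_span_rate > 0:
            n_spans = rng.poisson(spec.mask_span_rate * length / 1000.0)
            for _ in range(n_spans):
                start = int(rng.integers(0, length))
                span = int(rng.integers(20, 120))
                end = min(start + span, length)
                for p in range(start, end):
                    seq[p] = seq[p].lower()
                entry["mask_spans"].append([start, end])
        records.append((entry["id"], "".join(seq)))
        manifest.append(entry)
    return records, manifest


def _mutate(rng, seq: str, spec: FixtureSpec):
    """Apply substitutions/indels; returns (mutated, edit list)."""
    out = []
    edits = []
    i = 0
    for i, ch in enumerate(seq):
        r = rng.random()
        if spec.indel_rate > 0 and r < spec.indel_rate / 2:
            ln = int(rng.geometric(spec.indel_length_p))
            edits.append({"op": "del", "pos": i, "len": ln})
            continue  # deletion of this base (length handled approximately)
        if spec.indel_rate > 0 and r < spec.indel_rate:
            ins = _random_seq(rng, int(rng.geometric(spec.indel_length_p)),
                              spec.base_composition)
            out.append(ch)
            out.append(ins)
            edits.append({"op": "ins", "pos": i, "seq": ins})
            continue
        if r < spec.indel_rate + spec.substitution_rate:
            alt = [b for b in "ACGT" if b != ch.upper()]
            sub = alt[int(rng.integers(3))]
            out.append(sub)
            edits.append({"op": "sub", "pos": i, "to": sub})
        else:
            out.append(ch)
    return "".join(out), edits


def gen_queries(spec: FixtureSpec, database_records):
    """Background and planted queries plus a truth manifest.

    Planted queries copy a database window (either strand) and mutate it
    per the spec; the manifest records subject, strand, window and edits,
    so tests can assert recall of each planted homology.
    """
    rng = np.random.default_rng(spec.seed + 1)
    db = {sid: seq.upper() for sid, seq in database_records}
    records = []
    truth = []
    qlo, qhi = spec.query_length
    sids = sorted(db)
    for i in range(spec.n_queries):
        qid = f"query{i}"
        qlen = int(rng.integers(qlo, qhi + 1))
        if rng.random() < spec.planted_fraction:
            sid = sids[int(rng.integers(len(sids)))]
            subj = db[sid]
            wlen = min(qlen, len(subj))
            start = int(rng.integers(0, len(subj) - wlen + 1))
            window = subj[start : start + wlen]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                window = revcomp_str(window)
            seq, edits = _mutate(rng, window, spec)
            truth.append(
                {
                    "type": "planted",
                    "query": qid,
                    "subject": sid,
                    "strand": strand,
                    "s_start": start,
                    "s_end": start + wlen,
                    "length": wlen,
                    "edits": edits,
                }
            )
        else:
            seq = _random_seq(rng, qlen, spec.base_composition)
            truth.append({"type": "background", "query": qid})
        records.append((qid, seq))
    return records, truth


# -- plain-text emission ------------------------------------------------------


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_manifest(entries, path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")


# -- oracles used to self-verify constructions --------------------------------


def all_w_hits(query: str, subject: str, w: int):
    """Every (q, s_plus, strand) pair with an exact w-length match.

    Naive hash-of-windows enumeration over both strands; used to verify
    adversarial constructions and as the seeding ground truth.
    """
    hits = set()
    idx: dict[str, list[tuple[str, int]]] = {}
    rc = revcomp_str(subject)
    L = len(subject)
    for i in range(len(subject) - w + 1):
        idx.setdefault(subject[i : i + w], []).append(("+", i))
    for i in range(len(rc) - w + 1):
        idx.setdefault(rc[i : i + w], []).append(("-", i))
    for qi in range(len(query) - w + 1):
        for strand, si in idx.get(query[qi : qi + w], ()):
            hits.add((qi, si if strand == "+" else L - si - w, strand))
    return hits


# -- adversarial constructions ------------------------------------------------


def gen_adversarial(case_id: str, w: int = 28, k: int = 11, seed: int = 0):
    """Deterministic corner cases; each is self-verified by `all_w_hits`.

    Returns a dict with ``database`` records, ``query`` records and case
    metadata (the expected hits / behavior).
    """
    rng = np.random.default_rng(seed)
    if case_id == "stride_witness":
        # exactly one w-hit at query offset 1: found at stride w-k+1 where
        # sample point w-k+1 covers window starts [1, w-k+1]; missed at
        # stride w-k+2 whose sample points 0 and w-k+2 skip offset 1.
        for attempt in range(100):
            db = _random_seq(rng, 600, (0.25,) * 4)
            pos = int(rng.integers(50, 500))
            frag = db[pos : pos + w]
            query = (
                _random_seq(rng, 1, (0.25,) * 4)
                + frag
                + _random_seq(rng, 1, (0.25,) * 4)
            )
            hits = all_w_hits(query, db, w)
            if hits == {(1, pos, "+")}:
                return {
                    "database": [("adv_subject", db)],
                    "query": [("adv_query", query)],
                    "expected_hits": hits,
                    "w": w,
                    "k": k,
                }
        raise RuntimeError("could not construct stride witness")
    if case_id == "tandem_repeat":
        # period-6 repeat trimmed so shifted alignments are shorter than w:
        # every seed lands on the zero diagonal of the planted window.
        period = "ACGGTC"
        region_len = w + 4
        region = (period * ((region_len // len(period)) + 1))[:region_len]
        db = _random_seq(rng, 300, (0.25,) * 4) + region + _random_seq(rng, 300, (0.25,) * 4)
        query = region
        return {
            "database": [("adv_subject", db)],
            "query": [("adv_query", query)],
            "expected_diagonals": {300},
            "w": w,
            "k": k,
        }
    if case_id == "palindrome":
        # reverse-complement palindrome: the same window matches both strands
        half = _random_seq(rng, w // 2, (0.25,) * 4)
        pal = half + revcomp_str(half)
        db = _random_seq(rng, 200, (0.25,) * 4) + pal + _random_seq(rng, 200, (0.25,) * 4)
        return {
            "database": [("adv_subject", db)],
            "query": [("adv_query", pal)],
            "w": len(pal),
            "k": k,
        }
    if case_id == "edge_hit":
        # the only w-hit ends exactly at the last query symbol
        for attempt in range(100):
            db = _random_seq(rng, 500, (0.25,) * 4)
            pos = int(rng.integers(50, 400))
            query = _random_seq(rng, 37, (0.25,) * 4) + db[pos : pos + w]
            hits = all_w_hits(query, db, w)
            if hits == {(37, pos, "+")}:
                return {
                    "database": [("adv_subject", db)],
                    "query": [("adv_query", query)],
                    "expected_hits": hits,
                    "w": w,
                    "k": k,
                }
        raise RuntimeError("could not construct edge case")
    if case_id == "masked_straddle":
        # seed window straddles a soft-masked database span; the sampled
        # query k-mer is unmasked so the hit must still be found
        db = _random_seq(rng, 400, (0.25,) * 4)
        pos = 200
        frag = db[pos : pos + w]
        db_masked = db[: pos + w // 2] + db[pos + w // 2 : pos + w].lower() + db[pos + w :]
        query = _random_seq(rng, 30, (0.25,) * 4) + frag + _random_seq(rng, 30, (0.25,) * 4)
        return {
            "database": [("adv_subject", db_masked)],
            "query": [("adv_query", query)],
            "expected_hits": {(30, pos, "+")} if all_w_hits(query, db, w) == {(30, pos, "+")} else all_w_hits(query, db, w),
            "w": w,
            "k": k,
        }
    raise KeyError(f"unknown adversarial case {case_id!r}")
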