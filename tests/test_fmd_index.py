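import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmseek.alphabet import CHAR_TO_CODE, decode, encode_query, revcomp_str
from fmseek.fmd_index import (
    BiInterval,
    IndexFormatError,
    build_index,
    build_text,
    load_index,
    save_index,
    suffix_array,
)
from oracles import naive_count, naive_positions, naive_suffix_array

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def text_str(seq_text):
    return decode(seq_text.text)


# -- build_text ---------------------------------------------------------------


class TestBuildText:
    def test_palindromic_complement_segments(self):
        st_ = build_text([("s1", "ACGT")], rng_seed=0)
        assert text_str(st_).startswith("ACGT$ACGT$")

    def test_ambiguity_logged(self):
        st_ = build_text([("s1", "AAN")], rng_seed=7)
        assert any(
            sid == "s1" and off == 2 and orig == "N"
            for sid, off, orig, _repl in st_.ambiguity_log
        )

    def test_reverse_complement_segment(self):
        st_ = build_text([("s1", "GGC")], rng_seed=0)
        assert text_str(st_).startswith("GGC$GCC$")

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            build_text([], rng_seed=0)

    def test_bad_symbol_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            build_text([("s1", "AC!GT")], rng_seed=0)

    def test_deterministic_for_seed(self):
        a = build_text([("s1", "ANNNNC")], rng_seed=3)
        b = build_text([("s1", "ANNNNC")], rng_seed=3)
        assert np.array_equal(a.text, b.text)

    def test_every_subject_and_rc_present(self):
        st_ = build_text([("a", "ACCGT"), ("b", "TTGA")], rng_seed=0)
        s = text_str(st_)
        for frag in ("ACCGT$", "ACGGT$", "TTGA$", "TCAA$"):
            assert frag in s
        strands = {(seg.subject_id, seg.strand) for seg in st_.layout}
        assert strands == {("a", "+"), ("a", "-"), ("b", "+"), ("b", "-")}


# -- suffix array / build_index ----------------------------------------------


class TestBuildIndex:
    def test_spec_example_acg(self):
        t = np.array([CHAR_TO_CODE[c] for c in "ACG"] + [0], dtype=np.uint8)
        sa = suffix_array(t)
        assert sa.tolist() == [3, 0, 1, 2]
        assert decode(t[(sa - 1) % 4]) == "G$AC"

    def test_c_array_counts_smaller_symbols(self):
        st_ = build_text([("s", "ACG")], rng_seed=0)
        idx = build_index(st_, r=1)
        # C[a] = count of symbols strictly smaller than a in the text
        s = text_str(st_)
        for a, ch in enumerate("$ACGT"):
            assert idx.C[a] == sum(s.count(c) for c in "$ACGT"[:a])

    def test_r1_sampled_equals_full(self):
        st_ = build_text([("s", "ACGTTGCA")], rng_seed=0)
        idx = build_index(st_, r=1)
        assert np.array_equal(idx.sampled_sa, suffix_array(st_.text))

    @given(dna)
    @settings(max_examples=25, deadline=None)
    def test_sa_matches_naive_rotation_sort(self, seq):
        st_ = build_text([("s", seq)], rng_seed=0)
        sa = suffix_array(st_.text)
        assert sa.tolist() == naive_suffix_array(text_str(st_))

    def test_bwt_definition(self):
        st_ = build_text([("s", "GATTACA")], rng_seed=0)
        idx = build_index(st_, r=1)
        sa = suffix_array(st_.text)
        t = st_.text
        for i, p in enumerate(sa):
            expected = t[p - 1] if p > 0 else 0
            assert idx.bwt[i] == expected

    def test_occ_row_sums_to_n(self):
        st_ = build_text([("s", "CCGTAG")], rng_seed=0)
        idx = build_index(st_, r=2)
        assert int(idx.occ_all(idx.n).sum()) == idx.n

    def test_bad_r_rejected(self):
        st_ = build_text([("s", "ACGT")], rng_seed=0)
        with pytest.raises(ValueError):
            build_index(st_, r=0)


# -- extension primitives -----------------------------------------------------


class TestExtension:
    def test_empty_interval_partition(self, small_index):
        _, idx = small_index
        total = 0
        for a in (1, 2, 3, 4):
            total += idx.backward_ext(idx.empty_interval(), a).size
        n_sentinels = int((idx.sequence_text.text == 0).sum())
        assert total == idx.n - n_sentinels

    def test_empty_is_absorbing(self, small_index):
        _, idx = small_index
        empty = BiInterval(0, 0, 0)
        assert idx.backward_ext(empty, 1).size == 0
        assert idx.forward_ext(empty, 3).size == 0

    def test_backward_ext_matches_naive_count(self):
        st_ = build_text([("s", "AAAA")], rng_seed=0)
        idx = build_index(st_, r=1)
        s = text_str(st_)
        bi = idx.backward_ext(idx.backward_ext(idx.empty_interval(), 1), 1)
        assert bi.size == naive_count(s, "AA")

    def test_forward_equals_backward_complement_size(self, small_index):
        _, idx = small_index
        for a in (1, 2, 3, 4):
            f = idx.forward_ext(idx.empty_interval(), a)
            b = idx.backward_ext(idx.empty_interval(), 5 - a)
            assert f.size == b.size

    def test_forward_backward_commute(self):
        st_ = build_text([("s", "ACGTACGGTCA")], rng_seed=0)
        idx = build_index(st_, r=1)
        from itertools import product

        for pat in ["".join(p) for n in range(0, 4) for p in product("ACGT", repeat=n)]:
            mid = idx.search(pat) if pat else idx.empty_interval()
            if mid.size == 0:
                continue
            for a in (1, 2, 3, 4):
                for b in (1, 2, 3, 4):
                    fb = idx.forward_ext(idx.backward_ext(mid, a), b)
                    bf = idx.backward_ext(idx.forward_ext(mid, b), a)
                    assert fb == bf

    def test_monotone_refinement(self, small_index):
        _, idx = small_index
        bi = idx.empty_interval()
        for a in (2, 1, 4, 3, 1):
            nxt = idx.forward_ext(bi, a)
            assert nxt.size <= bi.size
            bi = nxt

    def test_symbol_out_of_alphabet_rejected(self, small_index):
        _, idx = small_index
        with pytest.raises(ValueError):
            idx.backward_ext(idx.empty_interval(), 7)

    def test_bi_interval_symmetry(self, small_index):
        db, idx = small_index
        rng = np.random.default_rng(0)
        for _ in range(40):
            ln = int(rng.integers(1, 12))
            p0 = int(rng.integers(0, len(db) - ln))
            pat = db[p0 : p0 + ln]
            assert idx.search(pat).size == idx.search(revcomp_str(pat)).size


# -- sa_lookup / locate -------------------------------------------------------


class TestLocate:
    @pytest.mark.parametrize("r", [1, 2, 8, 32])
    def test_sa_lookup_equals_full_sa(self, r):
        rng = np.random.default_rng(11)
        db = "".join(rng.choice(list("ACGT"), 250))
        st_ = build_text([("s", db)], rng_seed=0)
        idx = build_index(st_, r=r)
        full = suffix_array(st_.text)
        assert [idx.sa_lookup(k) for k in range(idx.n)] == full.tolist()

    def test_spec_example_acg_r2(self):
        st_ = build_text([("s", "ACG")], rng_seed=0)
        idx = build_index(st_, r=2)
        # single-subject text ACG$CGT$$; check against the naive sort of it
        full = naive_suffix_array(text_str(st_))
        assert [idx.sa_lookup(k) for k in range(idx.n)] == full

    def test_out_of_range_rejected(self, small_index):
        _, idx = small_index
        with pytest.raises(IndexError):
            idx.sa_lookup(idx.n)
        with pytest.raises(IndexError):
            idx.sa_lookup(-1)

    def test_locate_aaaa(self):
        st_ = build_text([("s", "AAAA")], rng_seed=0)
        idx = build_index(st_, r=2)
        bi = idx.search("AA")
        hits = idx.locate(bi)
        plus = sorted(off for sid, off, strand in hits if strand == "+")
        minus = [h for h in hits if h[2] == "-"]
        assert plus == [0, 1, 2]
        assert minus == []  # rc segment is TTTT

    def test_unique_full_subject(self, multi_index):
        dbs, idx = multi_index
        pat = dbs["gamma"]
        bi = idx.search(pat)
        assert idx.locate(bi) == [("gamma", 0, "+")]
        # the mirror occurrence sits in the reverse-complement interval
        mirror = BiInterval(bi.lower_rc, bi.lower, bi.size)
        assert idx.locate(mirror) == [("gamma", 0, "-")]

    def test_empty_interval_locates_nothing(self, small_index):
        _, idx = small_index
        assert idx.locate(BiInterval(0, 0, 0)) == []

    def test_locate_equals_naive_scan(self, multi_index):
        dbs, idx = multi_index
        s = text_str(idx.sequence_text)
        layout = {(g.subject_id, g.strand): g for g in idx.sequence_text.layout}
        rng = np.random.default_rng(5)
        for _ in range(30):
            ln = int(rng.integers(1, 15))
            p0 = int(rng.integers(0, len(s) - ln))
            pat = s[p0 : p0 + ln]
            if "$" in pat:
                continue
            bi = idx.search(pat)
            glob = sorted(
                layout[(sid, strand)].global_start + off
                for sid, off, strand in idx.locate(bi)
            )
            assert glob == naive_positions(s, pat)

    def test_lf_visits_every_position_once(self):
        st_ = build_text([("a", "ACGTTA"), ("b", "GGAT")], rng_seed=0)
        idx = build_index(st_, r=1)
        k = idx._rank_of_text_start
        seen = set()
        for _ in range(idx.n):
            assert k not in seen
            seen.add(k)
            k = idx.lf(k)
        assert len(seen) == idx.n


# -- persistence --------------------------------------------------------------


class TestPersistence:
    def make(self, tmp_path, seq="ACGTTGCANRY" * 90):
        st_ = build_text([("s", seq)], rng_seed=9)
        idx = build_index(st_, r=4)
        from fmseek.lookup_table import build_lookup

        build_lookup(idx, k=6)
        p = tmp_path / "bundle.fmseek"
        save_index(idx, p)
        return idx, p

    def test_round_trip_identity(self, tmp_path):
        idx, p = self.make(tmp_path)
        idx2 = load_index(p)
        assert [idx2.sa_lookup(k) for k in range(idx2.n)] == [
            idx.sa_lookup(k) for k in range(idx.n)
        ]
        for pat in ("ACG", "TTGCA", "GG"):
            assert idx.search(pat) == idx2.search(pat)
        assert np.array_equal(idx.lookup_table.size, idx2.lookup_table.size)
        assert idx2.sequence_text.rng_seed == 9
        assert idx2.sequence_text.ambiguity_log == idx.sequence_text.ambiguity_log

    def test_corrupt_magic(self, tmp_path):
        _, p = self.make(tmp_path)
        data = bytearray(p.read_bytes())
        data[0] ^= 0xFF
        p.write_bytes(bytes(data))
        with pytest.raises(IndexFormatError):
            load_index(p)

    def test_truncated_file(self, tmp_path):
        _, p = self.make(tmp_path)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(IndexFormatError):
            load_index(p)

    def test_save_deterministic(self, tmp_path):
        idx, p = self.make(tmp_path)
        p2 = tmp_path / "again.fmseek"
        save_index(idx, p2)
        assert p.read_bytes() == p2.read_bytes()
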