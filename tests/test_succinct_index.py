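"""Succinct index layer: suffix array, BWT, wavelet rank, backward search,
locate, auxiliary hash, packed text, serialization, accounting."""

import numpy as np
import pytest

from dbhash._bits import BitVector, WaveletTree
from dbhash.hashing import hash_text, hash_xor
from dbhash.simulate import random_genome
from dbhash.succinct_index import (
    DbHashIndex,
    PackedText,
    aux_depth_bound,
    build_aux_hash,
    build_suffix_array,
    bwt_from_sa,
    hamming_verify,
    pack_text,
)


class TestSuffixArrayAndBwt:
    def test_tiny_examples(self):
        assert build_suffix_array([1, 0, -1]).tolist() == [2, 1, 0]
        assert build_suffix_array([0, 0, 0, -1]).tolist() == [3, 2, 1, 0]

    def test_missing_sentinel_rejected(self):
        with pytest.raises(ValueError):
            build_suffix_array([1, 0, 2])
        with pytest.raises(ValueError):
            build_suffix_array([0, -1, -1])  # not unique

    def test_matches_naive_full_sort(self):
        rng = np.random.default_rng(1)
        S = np.concatenate([rng.integers(0, 4, 2000), [-1]])
        sa = build_suffix_array(S)
        naive = sorted(range(len(S)), key=lambda i: tuple(S[i:]))
        assert sa.tolist() == naive

    def test_bwt_example_and_permutation(self):
        S = np.array([1, 0, -1])
        bwt = bwt_from_sa(S, build_suffix_array(S))
        assert bwt.tolist() == [0, 1, -1]
        rng = np.random.default_rng(2)
        S = np.concatenate([rng.integers(0, 4, 500), [-1]])
        bwt = bwt_from_sa(S, build_suffix_array(S))
        assert sorted(bwt.tolist()) == sorted(S.tolist())

    def test_bwt_invertible(self):
        # reconstruct S by repeated LF-stepping from the sentinel row
        rng = np.random.default_rng(3)
        S = np.concatenate([rng.integers(0, 4, 200), [-1]])
        sa = build_suffix_array(S)
        bwt = bwt_from_sa(S, sa)
        n = len(S)
        order = np.argsort(bwt, kind="stable")  # maps F rank -> BWT row
        # standard inverse: walk LF starting from the row whose suffix is S itself
        counts = {}
        lf = np.empty(n, np.int64)
        symbols = sorted(set(bwt.tolist()))
        C = {}
        tot = 0
        for c in symbols:
            C[c] = tot
            tot += int((bwt == c).sum())
        seen = {c: 0 for c in symbols}
        for i, c in enumerate(bwt.tolist()):
            lf[i] = C[c] + seen[c]
            seen[c] += 1
        rec = []
        row = 0  # row of the sentinel-ending rotation in F order
        for _ in range(n):
            rec.append(int(bwt[row]))
            row = lf[row]
        # walking LF from the top row yields S backwards, sentinel last
        assert rec[::-1] == [-1] + S.tolist()[:-1]


class TestBitsAndWavelet:
    def test_bitvector_rank_matches_prefix_sums(self):
        rng = np.random.default_rng(4)
        bits = rng.random(777) < 0.3
        bv = BitVector(bits)
        cum = np.concatenate([[0], np.cumsum(bits)])
        for i in [0, 1, 63, 64, 65, 128, 300, 776, 777]:
            assert bv.rank1(i) == cum[i]
            assert bv.rank0(i) == i - cum[i]
        assert bv.to_array().tolist() == bits.tolist()

    def test_wavelet_rank_and_access_match_naive(self):
        rng = np.random.default_rng(5)
        sym = rng.integers(0, 4, 5000).astype(np.uint8)
        wt = WaveletTree(sym)
        check = rng.integers(0, 5001, 200)
        for i in check:
            i = int(i)
            for c in range(4):
                assert wt.rank(c, i) == int((sym[:i] == c).sum())
        for i in rng.integers(0, 5000, 200):
            assert wt.access(int(i)) == int(sym[int(i)])
        assert (wt.to_array() == sym).all()

    def test_wavelet_payload_is_two_bits_per_symbol(self):
        sym = np.random.default_rng(6).integers(0, 4, 6400).astype(np.uint8)
        wt = WaveletTree(sym)
        assert wt.payload_bits == 2 * 6400


@pytest.fixture(scope="module")
def fm_fixture():
    """Index on 2 kb of random sequence plus the naive h(T) string."""
    contigs = random_genome(2000, seed=9)
    idx = DbHashIndex.build(contigs, m=20, w=8)
    from dbhash.hashing import encode_sequence

    T = encode_sequence(contigs[0][1]).symbols
    hT = hash_text(T, idx.m, idx.w)
    return idx, hT


def naive_fingerprint_positions(hT, f):
    f = np.asarray(f, np.uint8)
    w = len(f)
    return [
        i for i in range(len(hT) - w + 1) if (hT[i : i + w] == f).all()
    ]


class TestBackwardSearchAndLocate:
    def test_empty_query_is_full_interval(self, fm_fixture):
        idx, _ = fm_fixture
        assert idx.backward_search([]) == (0, idx.hlen + 1)

    def test_absent_fingerprint_empty_interval(self, fm_fixture):
        idx, hT = fm_fixture
        # craft a fingerprint absent from h(T)
        rng = np.random.default_rng(10)
        while True:
            f = rng.integers(0, 4, idx.w).astype(np.uint8)
            if not naive_fingerprint_positions(hT, f):
                break
        lo, hi = idx.backward_search(f)
        assert lo == hi
        assert idx.lookup(f).size == 0

    def test_interval_size_and_locate_match_naive_scan(self, fm_fixture):
        idx, hT = fm_fixture
        rng = np.random.default_rng(11)
        for _ in range(200):
            if rng.random() < 0.7:
                p = int(rng.integers(0, idx.hlen - idx.w))
                f = hT[p : p + idx.w]
            else:
                f = rng.integers(0, 4, idx.w).astype(np.uint8)
            expected = naive_fingerprint_positions(hT, f)
            lo, hi = idx.backward_search(f)
            assert hi - lo == len(expected)
            assert idx.lookup(f).tolist() == expected

    @pytest.mark.parametrize("s", [1, 4, 16, 64])
    def test_locate_for_all_sampling_steps(self, s):
        contigs = random_genome(1500, seed=20 + s)
        idx = DbHashIndex.build(contigs, m=16, w=6, s=s)
        from dbhash.hashing import encode_sequence

        hT = hash_text(encode_sequence(contigs[0][1]).symbols, 16, 6)
        rng = np.random.default_rng(s)
        for _ in range(50):
            p = int(rng.integers(0, idx.hlen - idx.w))
            f = hT[p : p + idx.w]
            assert idx.lookup(f).tolist() == naive_fingerprint_positions(hT, f)

    def test_lookup_superset_of_exact_occurrences(self, fm_fixture):
        # a pattern occurrence in T implies a fingerprint occurrence in h(T)
        idx, hT = fm_fixture
        T = idx.packed.unpack()
        for pos in (0, 313, 777):
            P = T[pos : pos + idx.m]
            hits = idx.lookup(hash_xor(P, idx.w)).tolist()
            assert pos in hits


class TestAuxiliaryHash:
    def test_zero_depth_single_full_interval(self, fm_fixture):
        idx, _ = fm_fixture
        aux = build_aux_hash(idx, 0)
        assert aux.lo.tolist() == [0] and aux.hi.tolist() == [idx.hlen + 1]

    def test_entries_equal_direct_backward_search(self, fm_fixture):
        idx, _ = fm_fixture
        aux = build_aux_hash(idx, 2)
        assert aux.lo.size == 16
        for u in range(16):
            f = np.array([(u >> 2) & 3, u & 3], np.uint8)
            lo, hi = idx.backward_search(f, use_aux=False)
            assert (int(aux.lo[u]), int(aux.hi[u])) == (lo, hi)

    def test_intervals_partition_rows_without_sentinel_prefix(self, fm_fixture):
        idx, _ = fm_fixture
        d = 2
        aux = build_aux_hash(idx, d)
        covered = sorted(
            r for u in range(16) for r in range(int(aux.lo[u]), int(aux.hi[u]))
        )
        # the intervals are disjoint and cover every row except the d rows
        # whose length-d prefix runs into the sentinel (the d shortest suffixes)
        assert len(covered) == len(set(covered)) == idx.hlen + 1 - d
        assert 0 not in covered  # the sentinel suffix itself is never covered

    def test_depth_beyond_bound_rejected(self, fm_fixture):
        idx, _ = fm_fixture
        with pytest.raises(ValueError):
            build_aux_hash(idx, aux_depth_bound(idx.hlen) + 1)

    def test_lookup_transparent_to_aux(self, fm_fixture):
        idx, hT = fm_fixture
        rng = np.random.default_rng(13)
        for _ in range(100):
            f = rng.integers(0, 4, idx.w).astype(np.uint8)
            assert idx.lookup(f, use_aux=True).tolist() == idx.lookup(f, use_aux=False).tolist()


class TestPackedText:
    def test_roundtrip(self):
        rng = np.random.default_rng(14)
        T = rng.integers(0, 4, 1013).astype(np.uint8)
        pt = pack_text(T)
        assert (pt.unpack() == T).all()
        assert (pt.unpack(100, 57) == T[100:157]).all()

    def test_out_of_range_rejected(self):
        pt = pack_text(np.zeros(16, np.uint8))
        with pytest.raises(ValueError):
            pt.unpack(10, 10)
        with pytest.raises(ValueError):
            hamming_verify(pt, np.zeros(8, np.uint8), 12, 3)

    def test_verify_exact_and_constructed(self):
        rng = np.random.default_rng(15)
        T = rng.integers(0, 4, 300).astype(np.uint8)
        pt = pack_text(T)
        P = T[40:140].copy()
        assert hamming_verify(pt, P, 40, 0) == 0
        P[3] ^= 1
        P[77] ^= 2
        assert hamming_verify(pt, P, 40, 2) == 2
        assert hamming_verify(pt, P, 40, 1) is None  # early reject

    def test_verify_matches_naive_counter(self):
        rng = np.random.default_rng(16)
        T = rng.integers(0, 4, 5000).astype(np.uint8)
        pt = pack_text(T)
        for _ in range(10_000 // 10):  # 1000 random (window, query) pairs
            L = int(rng.integers(1, 130))
            pos = int(rng.integers(0, 5000 - L))
            P = T[pos : pos + L].copy()
            nmut = int(rng.integers(0, 6))
            sites = rng.choice(L, size=min(nmut, L), replace=False)
            P[sites] ^= rng.integers(1, 4, len(sites)).astype(np.uint8)
            naive = int(np.count_nonzero(T[pos : pos + L] != P))
            got = hamming_verify(pt, P, pos, 10**9)
            assert got == naive


class TestIndexBuildAndSerialization:
    def test_default_w_sizing(self):
        idx = DbHashIndex.build(random_genome(100_000, seed=17), m=20)
        import math

        assert idx.w == max(4, min(math.ceil(math.log(20 * 100_000, 4)), 20, 32))

    def test_short_contigs_skipped_with_warning(self, caplog):
        import logging

        contigs = [("tiny", "ACGT"), ("big", random_genome(500, seed=18)[0][1])]
        with caplog.at_level(logging.WARNING, logger="dbhash.succinct_index"):
            idx = DbHashIndex.build(contigs, m=16)
        assert [c.name for c in idx.contigs] == ["big"]
        assert any("skipping contig" in r.message for r in caplog.records)

    def test_all_contigs_too_short_rejected(self):
        with pytest.raises(ValueError):
            DbHashIndex.build([("a", "ACGT")], m=16)

    def test_duplicate_contig_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DbHashIndex.build([("a", "ACGT" * 10), ("a", "ACGT" * 10)], m=8)

    def test_save_load_roundtrip(self, tmp_path, fm_fixture):
        idx, hT = fm_fixture
        p1 = tmp_path / "x.dbh"
        p2 = tmp_path / "y.dbh"
        idx.save(p1)
        idx2 = DbHashIndex.load(p1)
        idx2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical save-load-save
        rng = np.random.default_rng(19)
        for _ in range(50):
            f = rng.integers(0, 4, idx.w).astype(np.uint8)
            assert idx.lookup(f).tolist() == idx2.lookup(f).tolist()
        assert [(c.name, c.length, c.offset) for c in idx.contigs] == [
            (c.name, c.length, c.offset) for c in idx2.contigs
        ]

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "junk.dbh"
        p.write_bytes(b"NOTANIDX" + b"\x00" * 64)
        with pytest.raises(ValueError, match="magic"):
            DbHashIndex.load(p)

    def test_megabase_payload_under_two_bytes_per_symbol(self):
        idx = DbHashIndex.build(random_genome(1_000_000, seed=21), m=20)
        rep = idx.memory_report()
        assert rep["total"] == sum(v for k, v in rep.items() if k != "total")
        assert idx.bytes_per_symbol() <= 2.0
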