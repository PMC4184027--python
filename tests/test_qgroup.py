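import numpy as np
import pytest

from qgmap.container import ContainerError
from qgmap.encoding import EncodedSequence, encode_sequence
from qgmap.qgroup import (
    ConfigError,
    build,
    group_and_bit,
    grouprank,
    indexpair,
    load_index,
    lookup_many,
    naive_qgram_positions,
    positions,
    save_index,
    size_ratio,
    worst_case_words,
)


def random_seq(rng, n):
    return EncodedSequence(rng.integers(0, 4, n).astype(np.uint8))


class TestBuild:
    def test_homopolymer(self):
        idx = build(encode_sequence("AAAA"), q=2)
        assert int(idx.I[0]) == 1  # only bit 0 (q-gram AA) set
        assert np.count_nonzero(idx.I) == 1
        assert sorted(idx.O.tolist()) == [0, 1, 2]

    def test_acgt_repeat(self):
        idx = build(encode_sequence("ACGTACGT"), q=2)
        assert idx.n_distinct == 4  # AC, CG, GT, TA
        assert idx.O.size == 7

    def test_q_too_large_for_word(self):
        with pytest.raises(ConfigError):
            build(encode_sequence("ACGT" * 10), q=17, w=32)

    def test_rebuild_is_bit_identical(self, rng):
        seq = random_seq(rng, 400)
        a, b = build(seq, q=4), build(seq, q=4)
        for x, y in ((a.I, b.I), (a.S, b.S), (a.S_prime, b.S_prime), (a.O, b.O)):
            assert np.array_equal(x, y)


class TestGroupAndBit:
    @pytest.mark.parametrize("g,w,expected", [
        (0, 32, (0, 0)),
        (33, 32, (1, 1)),
        (4 ** 16 - 1, 32, (134217727, 31)),
    ])
    def test_known(self, g, w, expected):
        assert group_and_bit(g, w) == expected


class TestGrouprank:
    @pytest.mark.parametrize("word,j,expected", [
        (0b1, 0, 0),
        (0b1011, 3, 2),
        (2 ** 32 - 1, 17, 17),  # saturated mask: identity
    ])
    def test_known(self, word, j, expected):
        assert grouprank(word, j) == expected


class TestIndexpair:
    def test_absent(self):
        idx = build(encode_sequence("AAAA"), q=2)
        assert indexpair(idx, 5) is None

    def test_homopolymer_interval(self):
        idx = build(encode_sequence("AAAA"), q=2)
        ks, ke = indexpair(idx, 0)
        assert ke - ks == 3

    @pytest.mark.parametrize("q", [2, 3, 5, 8])
    def test_set_equals_naive_scan(self, q, rng):
        seq = random_seq(rng, 1000)
        idx = build(seq, q=q)
        naive = naive_qgram_positions(seq, q)
        for g in range(min(4 ** q, 7000)):
            assert sorted(positions(idx, g).tolist()) == naive.get(g, [])

    def test_q16_spot_check(self, rng):
        seq = random_seq(rng, 2000)
        idx = build(seq, q=16)
        naive = naive_qgram_positions(seq, 16)
        for g, want in list(naive.items())[:50]:
            assert sorted(positions(idx, g).tolist()) == want
        ks, ke = lookup_many(idx, np.array(list(naive)[:50], dtype=np.uint64))
        assert np.array_equal(ke - ks, [len(naive[g]) for g in list(naive)[:50]])

    def test_lookup_many_matches_scalar(self, rng):
        seq = random_seq(rng, 600)
        idx = build(seq, q=4)
        gs = np.arange(4 ** 4, dtype=np.uint64)
        ks, ke = lookup_many(idx, gs)
        for g in range(4 ** 4):
            pair = indexpair(idx, int(g))
            if pair is None:
                assert ks[g] == ke[g]
            else:
                assert (ks[g], ke[g]) == pair


class TestHalfSampledS:
    @pytest.mark.parametrize("q", [2, 4, 6])
    def test_lookups_match_full_variant(self, q, rng):
        seq = random_seq(rng, 800)
        full = build(seq, q=q, half_sampled=False)
        half = build(seq, q=q, half_sampled=True)
        assert half.S.size < full.S.size
        for g in range(4 ** q):
            assert indexpair(full, g) == indexpair(half, g)
        gs = np.arange(4 ** q, dtype=np.uint64)
        assert all(np.array_equal(a, b)
                   for a, b in zip(lookup_many(full, gs), lookup_many(half, gs)))


class TestInvariants:
    @pytest.mark.parametrize("q", [2, 4, 6])
    def test_counting_invariants(self, q, rng):
        seq = random_seq(rng, 700)
        idx = build(seq, q=q)
        assert int(np.bitwise_count(idx.I).sum()) == idx.n_distinct
        assert idx.O.size == len(seq) - q + 1  # no skipped runs
        assert idx.S[0] == 0
        assert np.array_equal(np.diff(idx.S), np.bitwise_count(idx.I))
        assert idx.S_prime[-1] == idx.O.size

    def test_skipped_runs_reduce_o(self):
        seq = encode_sequence("ACGT" + "N" * 12 + "ACGT", n_run_threshold=10)
        idx = build(seq, q=4)
        assert idx.O.size == 2  # positions 0 and 16 only

    @pytest.mark.parametrize("q,n", [(3, 100), (6, 5000), (8, 200)])
    def test_size_bound(self, q, n, rng):
        seq = random_seq(rng, n)
        idx = build(seq, q=q)
        assert idx.total_words() <= worst_case_words(q, 32, n) + 2  # sentinels


class TestSizeModel:
    def test_k1_disadvantage_three_percent(self):
        assert size_ratio(1.0) == pytest.approx(1.03125)

    def test_break_even_at_16_over_15(self):
        assert size_ratio(16 / 15) == pytest.approx(1.0)

    def test_large_k_limit_one_sixteenth(self):
        assert size_ratio(1e12) == pytest.approx(1 / 16, rel=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            size_ratio(0)

    def test_worst_case_words_printed_formula(self):
        assert worst_case_words(16, 32, 10 ** 8) == 468_435_456
        assert worst_case_words(4, 32, 0) == 2 * (4 ** 4 // 32)

    def test_ratio_consistent_with_word_count(self):
        # analytic ratio vs the discrete word count, |T| large enough
        T = 10 ** 6
        for q in (10, 11, 12):
            K = 4 ** q / T
            discrete = worst_case_words(q, 32, T) / (4 ** q + T)
            assert discrete == pytest.approx(size_ratio(K), rel=0.01)


class TestSerialization:
    def test_roundtrip_with_canonical_o(self, rng, tmp_path):
        seq = random_seq(rng, 500)
        idx = build(seq, q=4)
        path = tmp_path / "x.qgidx"
        save_index(idx, path)
        back = load_index(path)
        assert back.q == idx.q and back.w == idx.w
        assert np.array_equal(back.I, idx.I)
        assert np.array_equal(back.S, idx.S)
        assert np.array_equal(back.S_prime, idx.S_prime)
        for g in range(4 ** 4):
            got = back_positions = sorted(positions(back, g).tolist())
            assert got == sorted(positions(idx, g).tolist())
        # canonical: each interval sorted ascending on disk
        for x in range(back.n_distinct):
            seg = back.O[back.S_prime[x]:back.S_prime[x + 1]]
            assert np.all(np.diff(seg.astype(np.int64)) >= 0)

    def test_truncated_file_fails_checksum(self, rng, tmp_path):
        idx = build(random_seq(rng, 300), q=3)
        path = tmp_path / "x.qgidx"
        save_index(idx, path)
        data = path.read_bytes()
        path.write_bytes(data[:-10])
        with pytest.raises(ContainerError):
            load_index(path)

    def test_wrong_magic(self, tmp_path):
        path = tmp_path / "junk"
        path.write_bytes(b"NOTANIDX" + b"\0" * 64)
        with pytest.raises(ContainerError, match="magic"):
            load_index(path)
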