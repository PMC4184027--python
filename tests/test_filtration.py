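import numpy as np
import pytest

from qgmap.encoding import EncodedSequence, encode_sequence, qgram_codes
from qgmap.filtration import (
    ReadRecord,
    dedup_candidates,
    generate_hits,
    generate_raw_hits,
    make_batch,
    make_batches,
)
from qgmap.qgroup import ConfigError, build, lookup_many
from qgmap.refindex import build_reference_index
from qgmap.simulate import simulate_genome, simulate_reads


def _records(seqs):
    return [ReadRecord(name=f"r{i}", seq=encode_sequence(s), qual="I" * len(s))
            for i, s in enumerate(seqs)]


def _random_dna(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestBatching:
    def test_slot_layout(self, rng):
        reads = [_random_dna(rng, n) for n in (100, 100, 80)]
        batch = make_batch(_records(reads))
        assert batch.slot_length == 100
        assert len(batch.concat) == 300
        assert (280, 300) in batch.concat.skipped_runs

    def test_buffer_sizes(self, rng):
        recs = _records([_random_dna(rng, 30) for _ in range(5)])
        batches = list(make_batches(iter(recs), q=4, buffer_size=2))
        assert [b.count for b in batches] == [2, 2, 1]

    def test_short_reads_skipped(self, rng):
        recs = _records([_random_dna(rng, 30), "ACG", _random_dna(rng, 30)])
        gen = make_batches(iter(recs), q=16, buffer_size=10)
        batches = []
        skipped = None
        while True:
            try:
                batches.append(next(gen))
            except StopIteration as stop:
                skipped = stop.value
                break
        assert skipped == 1
        assert batches[0].count == 2

    def test_no_qgram_spans_slot_boundary(self, rng):
        q = 5
        reads = [_random_dna(rng, n) for n in (20, 14, 17)]
        batch = make_batch(_records(reads))
        idx = build(batch.concat, q=q)
        slot = batch.slot_length
        for o in idx.O.tolist():
            rid, off = divmod(o, slot)
            assert off + q <= len(reads[rid])


class TestGenerateHits:
    def test_unique_substring_single_diagonal(self, rng):
        genome = _random_dna(rng, 5000)
        start = 500
        read = genome[start:start + 100]
        ref = build_reference_index([("c", genome)], q=16, masking=False)
        batch = make_batch(_records([read]))
        idx = build(batch.concat, q=16)
        c = ref.chromosomes[0]
        raw_rid, raw_diag = generate_raw_hits(idx, batch, c.p_gram, c.p_pos)
        assert raw_diag.size == 100 - 16 + 1  # every read q-gram matches once
        assert set(raw_diag.tolist()) == {start}
        rid, diag = generate_hits(idx, batch, c.p_gram, c.p_pos)
        assert rid.tolist() == [0] and diag.tolist() == [start]

    def test_absent_read_no_hits(self, rng):
        genome = _random_dna(rng, 1_000_00)
        read = _random_dna(np.random.default_rng(999), 100)
        ref = build_reference_index([("c", genome)], q=16, masking=False)
        batch = make_batch(_records([read]))
        idx = build(batch.concat, q=16)
        c = ref.chromosomes[0]
        rid, diag = generate_hits(idx, batch, c.p_gram, c.p_pos)
        # sanity: the random read shares no 16-gram with the genome
        ref_grams = set(c.p_gram.tolist())
        read_grams = set(qgram_codes(batch.concat.codes[:100], 16).tolist())
        assert not (ref_grams & read_grams)
        assert rid.size == 0

    def test_empty_p_gives_empty_hits(self, rng):
        batch = make_batch(_records([_random_dna(rng, 50)]))
        idx = build(batch.concat, q=8)
        rid, diag = generate_hits(idx, batch, np.empty(0, np.uint64), np.empty(0, np.uint32))
        assert rid.size == 0

    def test_q_mismatch_rejected(self, rng):
        batch = make_batch(_records([_random_dna(rng, 50)]))
        idx = build(batch.concat, q=8)
        with pytest.raises(ConfigError):
            generate_hits(idx, batch, np.empty(0, np.uint64), np.empty(0, np.uint32), q=9)

    def test_raw_multiset_equals_naive_double_loop(self, rng):
        q = 4
        genome = _random_dna(rng, 300)
        reads = [_random_dna(rng, 25) for _ in range(6)]
        ref = build_reference_index([("c", genome)], q=q, masking=False)
        batch = make_batch(_records(reads))
        idx = build(batch.concat, q=q)
        c = ref.chromosomes[0]
        rid, diag = generate_raw_hits(idx, batch, c.p_gram, c.p_pos)
        got = sorted(zip(rid.tolist(), diag.tolist()))
        # oracle: all (reference q-gram) x (naive read-q-gram occurrence) pairs
        want = []
        for p in range(len(genome) - q + 1):
            gram = genome[p:p + q]
            for r, read in enumerate(reads):
                for o in range(len(read) - q + 1):
                    if read[o:o + q] == gram:
                        want.append((r, p - o))
        assert got == sorted(want)

    def test_compaction_size_equals_count_sum(self, rng):
        q = 3
        genome = _random_dna(rng, 200)
        reads = [_random_dna(rng, 20) for _ in range(4)]
        ref = build_reference_index([("c", genome)], q=q, masking=False)
        batch = make_batch(_records(reads))
        idx = build(batch.concat, q=q)
        c = ref.chromosomes[0]
        ks, ke = lookup_many(idx, c.p_gram)
        rid, diag = generate_raw_hits(idx, batch, c.p_gram, c.p_pos)
        assert rid.size == int((ke - ks).sum())


class TestDedup:
    def test_exact_duplicates_collapse(self):
        rid = np.array([0, 0, 0, 1])
        diag = np.array([10, 10, 10, 10])
        r, d = dedup_candidates(rid, diag, delta=0)
        assert list(zip(r.tolist(), d.tolist())) == [(0, 10), (1, 10)]

    def test_nearby_diagonals_merge(self):
        rid = np.zeros(4, dtype=np.int64)
        diag = np.array([10, 12, 13, 30])
        r, d = dedup_candidates(rid, diag, delta=3)
        assert d.tolist() == [10, 30]

    def test_negative_diagonal_clamped(self):
        r, d = dedup_candidates(np.array([0]), np.array([-7]), delta=3)
        assert d.tolist() == [0]


class TestPigeonhole:
    def test_guaranteed_diagonal_under_error_bound(self):
        """A length-n read with e < (n+1)/q - 1 substitutions must share a
        q-gram with its origin, so filtration emits the true diagonal."""
        q, n = 16, 100
        max_e = int(np.ceil((n + 1) / q - 1)) - 1  # e <= 5 for n=100, q=16
        genome = simulate_genome(200_000, seed=11)
        rng = np.random.default_rng(42)
        ref = build_reference_index([("c", genome)], q=q, masking=False)
        c = ref.chromosomes[0]
        # plant exactly max_e substitutions per read, forward strand
        reads = []
        starts = []
        for i in range(50):
            start = int(rng.integers(0, len(genome) - n))
            window = list(genome[start:start + n])
            for at in rng.choice(n, size=max_e, replace=False):
                window[at] = "ACGT"[("ACGT".index(window[at]) + 1) % 4]
            reads.append("".join(window))
            starts.append(start)
        batch = make_batch(_records(reads))
        idx = build(batch.concat, q=q)
        rid, diag = generate_hits(idx, batch, c.p_gram, c.p_pos, delta=0)
        found = set(zip(rid.tolist(), diag.tolist()))
        for i, start in enumerate(starts):
            assert (i, start) in found
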