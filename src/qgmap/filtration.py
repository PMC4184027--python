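"""Filtration: index the reads, stream the reference, emit candidate diagonals.

Reads are collected into batches and concatenated into fixed-length slots
(slot length = longest read in the batch); a q-group index is built once per
batch over the concatenation. Each chromosome's (q-gram, position) stream is
then probed against that index: every occurrence ``o`` of a reference q-gram
inside the read concatenation yields a read number ``o // slot_length`` and
a *hit diagonal* ``p - (o mod slot_length)`` — the putative start of the
read on the reference. The per-position hit counts, their exclusive prefix
sum and a compaction pass mirror the count/scan/scatter structure of the
parallel formulation; candidates are then deduplicated per (read, strand,
diagonal) with nearby diagonals merged to tolerate small indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodedSequence
from .qgroup import ConfigError, QGroupIndex, lookup_many

__all__ = ["ReadRecord", "ReadBatch", "make_batches", "make_batch",
           "generate_raw_hits", "dedup_candidates", "generate_hits"]

log = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    name: str
    seq: EncodedSequence
    qual: str = ""
    mate: int = 0       # 0 = single-end, 1/2 = paired mate number
    pair_id: int = -1   # index of the fragment in paired mode
    raw_seq: str = ""   # original letters, for SAM SEQ output


@dataclass
class ReadBatch:
    """Reads padded into fixed-length slots and concatenated for indexing."""

    records: list[ReadRecord]
    slot_length: int
    concat: EncodedSequence

    @property
    def count(self) -> int:
        return len(self.records)

    def read_length(self, read_id: int) -> int:
        return len(self.records[read_id].seq)


def make_batch(records: list[ReadRecord]) -> ReadBatch:
    """Concatenate reads into slots; padding is marked unindexable.

    Slot padding (and any long-N run inside a read) becomes a skipped run of
    the concatenation, so no q-gram ever spans two reads or enters padding.
    """
    if not records:
        raise ValueError("empty batch")
    slot = max(len(r.seq) for r in records)
    codes = np.zeros(slot * len(records), dtype=np.uint8)
    runs: list[tuple[int, int]] = []
    for i, rec in enumerate(records):
        off = i * slot
        n = len(rec.seq)
        codes[off : off + n] = rec.seq.codes
        for a, b in rec.seq.skipped_runs:
            runs.append((off + a, off + b))
        if n < slot:
            runs.append((off + n, off + slot))
        else:
            # zero-length run = cut point: no q-gram may cross the boundary
            runs.append((off + slot, off + slot))
    concat = EncodedSequence(codes, skipped_runs=sorted(runs))
    return ReadBatch(records=records, slot_length=slot, concat=concat)


def make_batches(records, q: int, buffer_size: int):
    """Yield successive ReadBatch objects of at most ``buffer_size`` reads.

    Reads shorter than q are skipped (logged and counted); the final yield
    reports the skip count via the generator's return value.
    """
    buf: list[ReadRecord] = []
    skipped = 0
    for rec in records:
        if len(rec.seq) < q:
            skipped += 1
            log.warning("read %s shorter than q=%d: skipped", rec.name, q)
            continue
        buf.append(rec)
        if len(buf) == buffer_size:
            yield make_batch(buf)
            buf = []
    if buf:
        yield make_batch(buf)
    return skipped


def generate_raw_hits(
    batch_index: QGroupIndex,
    batch: ReadBatch,
    p_gram: np.ndarray,
    p_pos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-dedup hit multiset for one chromosome strand stream.

    Two-pass structure: per-reference-position hit counts, exclusive prefix
    sum, then compaction of every occurrence into its interval of the output
    (output size is exactly the sum of the counts).
    """
    ks, ke = lookup_many(batch_index, p_gram)
    counts = ke - ks
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    excl = np.concatenate(([0], np.cumsum(counts)[:-1]))  # exclusive prefix sum
    rep_ks = np.repeat(ks, counts)
    within = np.arange(total, dtype=np.int64) - np.repeat(excl, counts)
    occ = batch_index.O[rep_ks + within].astype(np.int64)
    p_rep = np.repeat(p_pos.astype(np.int64), counts)
    read_id = occ // batch.slot_length
    offset = occ - read_id * batch.slot_length
    diagonal = p_rep - offset
    assert diagonal.size == total
    return read_id, diagonal


def dedup_candidates(
    read_id: np.ndarray, diagonal: np.ndarray, delta: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate (read, diagonal) pairs; merge diagonals within ±delta.

    Clusters of matching q-grams along one alignment produce runs of equal or
    near-equal diagonals; one representative (the smallest diagonal of each
    chain) survives. Negative diagonals (reads overhanging the contig start)
    are clamped to 0.
    """
    if read_id.size == 0:
        return read_id, diagonal
    diagonal = np.maximum(diagonal, 0)
    order = np.lexsort((diagonal, read_id))
    rid = read_id[order]
    dia = diagonal[order]
    keep = np.concatenate(([True], (rid[1:] != rid[:-1]) | (np.diff(dia) > delta)))
    return rid[keep], dia[keep]


def generate_hits(
    batch_index: QGroupIndex,
    batch: ReadBatch,
    p_gram: np.ndarray,
    p_pos: np.ndarray,
    delta: int = 3,
    q: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate (read_id, diagonal) pairs for one strand stream, deduplicated."""
    if q is not None and q != batch_index.q:
        raise ConfigError(
            f"reference stream q={q} does not match batch index q={batch_index.q}"
        )
    rid, dia = generate_raw_hits(batch_index, batch, p_gram, p_pos)
    return dedup_candidates(rid, dia, delta=delta)
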