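"""Precomputed reference stream: per-chromosome sorted (q-gram, position) pairs.

During mapping the reads are indexed and the *reference* is streamed against
them, so the reference side is prepared once: for each chromosome (and its
reverse complement, for minus-strand hits) the set ``P`` of (q-gram code,
position) pairs, sorted by numeric code, with exceedingly frequent q-grams
masked out. Sorting by code makes downstream index probes locally coherent;
masking bounds the candidate volume on repetitive sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .container import load_container, save_container
from .encoding import (
    EncodedSequence,
    encode_sequence,
    indexable_positions,
    qgram_codes,
    reverse_complement,
)

__all__ = ["ChromosomeIndex", "ReferenceIndex", "build_reference_index",
           "save_reference_index", "load_reference_index", "read_fasta"]

log = logging.getLogger(__name__)


@dataclass
class ChromosomeIndex:
    name: str
    seq: EncodedSequence
    p_gram: np.ndarray       # uint64, sorted ascending (ties: position ascending)
    p_pos: np.ndarray        # uint32, parallel to p_gram
    masked_qgrams: np.ndarray
    p_gram_rc: np.ndarray    # same stream over the reverse complement
    p_pos_rc: np.ndarray
    masked_qgrams_rc: np.ndarray
    mask_threshold: int | None

    _rc_seq: EncodedSequence | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def rc_seq(self) -> EncodedSequence:
        if self._rc_seq is None:
            self._rc_seq = reverse_complement(self.seq)
        return self._rc_seq


@dataclass
class ReferenceIndex:
    q: int
    chromosomes: list[ChromosomeIndex]
    absolute_cap: int
    frequency_cap: float
    masking: bool
    seed: int

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


def _stream(seq: EncodedSequence, q: int, threshold: int | None):
    """Sorted, masked (g, position) pairs for one strand of one chromosome."""
    pos = indexable_positions(seq, q)
    if pos.size == 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, dtype=np.uint32), empty
    gs = qgram_codes(seq.codes, q)[pos]
    order = np.argsort(gs, kind="stable")  # stable: ties stay position-ascending
    g_sorted = gs[order]
    p_sorted = pos[order].astype(np.uint32)
    new = np.concatenate(([True], g_sorted[1:] != g_sorted[:-1]))
    starts = np.flatnonzero(new)
    counts = np.diff(np.concatenate((starts, [g_sorted.size])))
    if threshold is None:
        return g_sorted, p_sorted, np.empty(0, dtype=np.uint64)
    masked = g_sorted[starts[counts > threshold]]
    keep = np.repeat(counts <= threshold, counts)
    return g_sorted[keep], p_sorted[keep], masked


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def build_reference_index(
    source: "str | Path | list[tuple[str, str]]",
    q: int,
    absolute_cap: int = 1000,
    frequency_cap: float = 1e-4,
    masking: bool = True,
    seed: int = 0,
    n_run_threshold: int = 10,
) -> ReferenceIndex:
    """Build the reference index from a FASTA path or (name, sequence) pairs.

    The per-chromosome mask threshold is ``max(absolute_cap,
    ceil(frequency_cap * length))``; q-grams occurring more often are dropped
    from ``P`` (``masking=False`` disables this entirely). Ambiguity
    replacement is seeded, so rebuilding with the same seed is deterministic.
    """
    records = read_fasta(source) if isinstance(source, (str, Path)) else list(source)
    if not records:
        raise ValueError("empty reference: no sequences given")
    if not any(len(s) >= q for _, s in records):
        raise ValueError(f"no reference sequence is at least q={q} bases long")
    chroms = []
    for idx, (name, raw) in enumerate(records):
        seq = encode_sequence(raw, rng_seed=(seed * 1_000_003 + idx) % (2**31), n_run_threshold=n_run_threshold)
        if len(seq) < q:
            log.warning("chromosome %s shorter than q=%d: empty q-gram stream", name, q)
        threshold = None
        if masking:
            threshold = max(absolute_cap, math.ceil(frequency_cap * len(seq)))
        g, p, m = _stream(seq, q, threshold)
        rc = reverse_complement(seq)
        g_rc, p_rc, m_rc = _stream(rc, q, threshold)
        chroms.append(ChromosomeIndex(
            name=name, seq=seq, p_gram=g, p_pos=p, masked_qgrams=m,
            p_gram_rc=g_rc, p_pos_rc=p_rc, masked_qgrams_rc=m_rc,
            mask_threshold=threshold, _rc_seq=rc,
        ))
    return ReferenceIndex(q=q, chromosomes=chroms, absolute_cap=absolute_cap,
                          frequency_cap=frequency_cap, masking=masking, seed=seed)


_KIND = "reference-index"


def save_reference_index(ref: ReferenceIndex, path: str | Path) -> None:
    meta = {
        "q": ref.q, "absolute_cap": ref.absolute_cap,
        "frequency_cap": ref.frequency_cap, "masking": ref.masking,
        "seed": ref.seed,
        "chromosomes": [
            {"name": c.name, "length": c.length, "mask_threshold": c.mask_threshold,
             "skipped_runs": [list(r) for r in c.seq.skipped_runs]}
            for c in ref.chromosomes
        ],
    }
    arrays: dict[str, np.ndarray] = {}
    for i, c in enumerate(ref.chromosomes):
        arrays[f"c{i}.codes"] = c.seq.codes
        arrays[f"c{i}.nmask"] = c.seq.n_mask
        arrays[f"c{i}.pg"] = c.p_gram
        arrays[f"c{i}.pp"] = c.p_pos
        arrays[f"c{i}.masked"] = c.masked_qgrams
        arrays[f"c{i}.pg_rc"] = c.p_gram_rc
        arrays[f"c{i}.pp_rc"] = c.p_pos_rc
        arrays[f"c{i}.masked_rc"] = c.masked_qgrams_rc
    save_container(path, _KIND, meta, arrays)


def load_reference_index(path: str | Path) -> ReferenceIndex:
    meta, arrays = load_container(path, _KIND)
    chroms = []
    for i, cm in enumerate(meta["chromosomes"]):
        seq = EncodedSequence(
            arrays[f"c{i}.codes"],
            arrays[f"c{i}.nmask"].astype(np.int64),
            [tuple(r) for r in cm["skipped_runs"]],
        )
        chroms.append(ChromosomeIndex(
            name=cm["name"], seq=seq,
            p_gram=arrays[f"c{i}.pg"].astype(np.uint64),
            p_pos=arrays[f"c{i}.pp"].astype(np.uint32),
            masked_qgrams=arrays[f"c{i}.masked"].astype(np.uint64),
            p_gram_rc=arrays[f"c{i}.pg_rc"].astype(np.uint64),
            p_pos_rc=arrays[f"c{i}.pp_rc"].astype(np.uint32),
            masked_qgrams_rc=arrays[f"c{i}.masked_rc"].astype(np.uint64),
            mask_threshold=cm["mask_threshold"],
        ))
    return ReferenceIndex(q=meta["q"], chromosomes=chroms,
                          absolute_cap=meta["absolute_cap"],
                          frequency_cap=meta["frequency_cap"],
                          masking=meta["masking"], seed=meta["seed"])
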