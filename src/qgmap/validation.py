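"""Validation: bit-parallel semi-global edit distance around candidate diagonals.

Each candidate diagonal is expanded to a reference window
``[diagonal - pad, diagonal + |r| + pad]`` with ``pad = band_width // 2``;
the window extent is what realizes the diagonal band: any alignment path
inside it deviates at most ``pad`` columns from the candidate diagonal, so
the maximum insertion or deletion size is bounded by the band while
mismatches are unaffected.

The distance itself is computed with the bit-parallel column recurrence of
Myers: the vertical delta of each edit-matrix column is held in two bit
vectors (VP/VN), one bit per read base, and a column transition is a
constant number of word operations. Python integers serve as the
(multi-word) bit vectors, so read length is not capped by a 32-bit word;
the semantics are those of the single-word banded formulation. The
semi-global boundary (free start in the reference) is the zero carry into
the horizontal delta. A second, reversed pass locates the best alignment
start. Hits are kept when their percent identity ``100 * (|r| - k) / |r|``
reaches the threshold (default 80).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .encoding import EncodedSequence
from .filtration import ReadBatch

__all__ = ["ValidatedHit", "banded_myers_distance", "myers_semiglobal",
           "locate_start", "validate_hits", "dedup_validated"]


@dataclass
class ValidatedHit:
    """A candidate confirmed by alignment scoring.

    Coordinates are 0-based half-open on the *forward* strand of the
    chromosome once the pipeline has converted them; inside validation they
    are local to the streamed (possibly reverse-complemented) sequence.
    """

    read_id: int
    strand: str           # '+' or '-'
    chrom: str
    ref_start: int
    ref_end: int
    k: int                # unit-cost semi-global edit distance
    read_len: int

    @property
    def s(self) -> float:
        """Percent identity, 100 * (|r| - k) / |r|."""
        return 100.0 * (self.read_len - self.k) / self.read_len

    @property
    def s_exact(self) -> Fraction:
        """Percent identity as an exact rational, for stratum grouping."""
        return Fraction(100 * (self.read_len - self.k), self.read_len)


def _peq(read_codes: np.ndarray) -> list[int]:
    """Per-symbol match masks: bit i of peq[c] set iff read[i] == c."""
    peq = [0, 0, 0, 0]
    for i, c in enumerate(read_codes):
        peq[c] |= 1 << i
    return peq


def myers_semiglobal(read_codes: np.ndarray, window_codes: np.ndarray) -> tuple[int, int]:
    """Minimum semi-global edit distance of the read against the window.

    The read must align end to end; the matching substring of the window is
    free to start and end anywhere. Returns ``(k, end_pos)`` with ``end_pos``
    the half-open window offset where the best alignment ends (the leftmost
    one on ties).
    """
    m = int(len(read_codes))
    if m == 0:
        return 0, 0
    peq = _peq(np.asarray(read_codes, dtype=np.uint8))
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    vp = mask
    vn = 0
    score = m
    best = m
    best_end = 0
    for j, c in enumerate(np.asarray(window_codes, dtype=np.uint8)):
        eq = peq[c]
        xv = eq | vn
        xh = (((eq & vp) + vp) ^ vp) | eq
        hp = vn | ~(xh | vp)
        hn = vp & xh
        if hp & high:
            score += 1
        elif hn & high:
            score -= 1
        hp = (hp << 1) & mask  # carry-in 0: text prefix is free (semi-global)
        hn = (hn << 1) & mask
        vp = (hn | ~(xv | hp)) & mask
        vn = hp & xv
        if score < best:
            best = score
            best_end = j + 1
    return best, best_end


def banded_myers_distance(
    read_codes: np.ndarray, ref_window: np.ndarray, band_width: int = 32
) -> tuple[int, int]:
    """Banded semi-global distance: the band is the window itself.

    The caller anchors the window on the candidate diagonal with
    ``band_width // 2`` columns of slack on each side, so every path the
    recurrence can score stays within the diagonal band; the result equals
    the unbanded optimum whenever the optimal path's excursion fits.
    """
    window = np.asarray(ref_window, dtype=np.uint8)
    limit = len(read_codes) + band_width
    if window.shape[0] > limit:
        window = window[:limit]
    return myers_semiglobal(read_codes, window)


def locate_start(
    read_codes: np.ndarray, ref_window: np.ndarray, k: int, end_pos: int
) -> int:
    """Best alignment start, via the same recurrence run backwards.

    Reversing the read and the window prefix ending at ``end_pos`` turns the
    free-end search into a free-start search; among starts achieving the
    forward distance the smallest one is returned.
    """
    rev_read = np.asarray(read_codes, dtype=np.uint8)[::-1]
    rev_win = np.asarray(ref_window, dtype=np.uint8)[:end_pos][::-1]
    m = int(len(rev_read))
    if m == 0:
        return end_pos
    peq = _peq(rev_read)
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    vp, vn = mask, 0
    score = m
    best = m
    best_extent = 0
    for j, c in enumerate(rev_win):
        eq = peq[c]
        xv = eq | vn
        xh = (((eq & vp) + vp) ^ vp) | eq
        hp = vn | ~(xh | vp)
        hn = vp & xh
        if hp & high:
            score += 1
        elif hn & high:
            score -= 1
        hp = (hp << 1) & mask
        hn = (hn << 1) & mask
        vp = (hn | ~(xv | hp)) & mask
        vn = hp & xv
        if score <= best:  # ties -> longest extent -> smallest start
            best = score
            best_extent = j + 1
    if best != k:
        raise AssertionError(f"backward pass distance {best} != forward distance {k}")
    return end_pos - best_extent


def validate_hits(
    candidates: tuple[np.ndarray, np.ndarray],
    batch: ReadBatch,
    ref_seq: EncodedSequence,
    chrom: str,
    strand: str,
    identity_threshold: float = 80.0,
    band_width: int = 32,
) -> list[ValidatedHit]:
    """Score candidate diagonals; keep hits with percent identity >= threshold.

    Coordinates in the returned hits are local to ``ref_seq`` (the forward
    or reverse-complemented chromosome the candidates were generated on).
    """
    read_ids, diagonals = candidates
    ref_codes = ref_seq.codes
    ref_len = len(ref_seq)
    pad = band_width // 2
    out: list[ValidatedHit] = []
    for rid, diag in zip(read_ids.tolist(), diagonals.tolist()):
        read_codes = batch.records[rid].seq.codes
        rlen = len(read_codes)
        win_lo = max(0, diag - pad)
        win_hi = min(ref_len, diag + rlen + pad)
        if win_hi <= win_lo:
            continue
        window = ref_codes[win_lo:win_hi]
        k, end = banded_myers_distance(read_codes, window, band_width=band_width)
        # exact rational comparison: s >= threshold  <=>  100*(|r|-k) >= thr*|r|
        if 100 * (rlen - k) < identity_threshold * rlen:
            continue
        start = locate_start(read_codes, window, k, end)
        out.append(ValidatedHit(
            read_id=rid, strand=strand, chrom=chrom,
            ref_start=win_lo + start, ref_end=win_lo + end,
            k=k, read_len=rlen,
        ))
    return out


def dedup_validated(hits: list[ValidatedHit]) -> list[ValidatedHit]:
    """Collapse hits of one read sharing (strand, chrom, ref_start); keep best k."""
    best: dict[tuple[int, str, str, int], ValidatedHit] = {}
    for h in hits:
        key = (h.read_id, h.strand, h.chrom, h.ref_start)
        cur = best.get(key)
        if cur is None or (h.k, h.ref_end) < (cur.k, cur.ref_end):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.read_id, h.chrom, h.ref_start, h.strand))
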