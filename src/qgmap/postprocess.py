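"""Postprocessing: strata, mapping quality, mate pairing and alignment traceback.

Validated hits of a read are grouped into *strata* of equal percent identity
(exact rational comparison on ``(|r| - k, |r|)`` — no float-equality
artifacts); reporting keeps either all strata or only the best one. The
mapping quality of a hit is the PHRED-scaled posterior that it is the read's
true origin: the sampling likelihood is approximated as ``C * exp(-lambda *
kappa)`` with ``kappa = 100 - s`` the alignment error rate, normalized over
the read's validated hits, capped at 60 and forced to 0 when two or more
best hits tie. The actual alignment (CIGAR) is recovered by a unit-cost DP
traceback over the validated span, in semi-global or soft-clipping local
style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .validation import ValidatedHit

__all__ = ["HitStratum", "MappingQualityModel", "build_strata",
           "mapping_quality", "pair_mates", "traceback_alignment",
           "cigar_to_string"]


@dataclass
class MappingQualityModel:
    lam: float = 1.0          # decay rate of the sampling likelihood
    const: float = 1.0        # likelihood scale C (cancels in the posterior)
    cap: int = 60             # PHRED cap


@dataclass
class HitStratum:
    score: Fraction           # percent identity (or summed identity for pairs)
    hits: list = field(default_factory=list)
    rank: int = 0             # 0 = best stratum


def build_strata(hits: list[ValidatedHit], mode: str = "best-stratum") -> list[HitStratum]:
    """Group one read's hits into strata ordered by percent identity, descending.

    ``mode='all'`` retains every stratum, ``mode='best-stratum'`` only the
    top one. Pair-level strata (summed identities) are built by the caller
    from pair entities; this function handles one hit list.
    """
    if mode not in ("all", "best-stratum"):
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[Fraction, list[ValidatedHit]] = {}
    for h in hits:
        groups.setdefault(h.s_exact, []).append(h)
    strata = [HitStratum(score=s, hits=hs, rank=r)
              for r, (s, hs) in enumerate(sorted(groups.items(), key=lambda kv: -kv[0]))]
    if mode == "best-stratum":
        strata = strata[:1]
    return strata


def mapping_quality(
    hits: list[ValidatedHit],
    model: MappingQualityModel | None = None,
    ambiguous_best: bool | None = None,
) -> list[int]:
    """PHRED mapping quality per hit, from the posterior over validated hits.

    ``Pr(p|r) = L_p / sum(L)`` with ``L_p = C * exp(-lambda * (100 - s_p))``;
    quality = ``min(floor(-10 * log10(1 - Pr)), cap)``, with the cap applied
    directly when the posterior is 1. If two or more hits tie at the best
    percent identity (or ``ambiguous_best`` is forced by a pair-level rule),
    every tied-best hit is assigned 0.
    """
    if not hits:
        return []
    model = model or MappingQualityModel()
    exact = [h.s_exact for h in hits]
    best = max(exact)
    n_best = sum(1 for s in exact if s == best)
    if ambiguous_best is None:
        ambiguous_best = n_best >= 2
    likes = [model.const * math.exp(-model.lam * (100.0 - h.s)) for h in hits]
    total = sum(likes)
    out = []
    for h, s, like in zip(hits, exact, likes):
        if ambiguous_best and s == best:
            out.append(0)
            continue
        pr = like / total
        if pr >= 1.0:
            q = model.cap
        else:
            q = min(math.floor(-10.0 * math.log10(1.0 - pr)), model.cap)
        out.append(max(0, int(q)))
    return out


def pair_mates(
    hits1: list[ValidatedHit],
    hits2: list[ValidatedHit],
    insert_min: int,
    insert_max: int,
) -> tuple[list[tuple[ValidatedHit, ValidatedHit]], list[ValidatedHit], list[ValidatedHit]]:
    """Greedy proper pairing of the two mates' hits.

    A pairing is proper iff both hits share the chromosome, lie on opposite
    strands in forward-reverse orientation (the leftmost mate on '+'), and
    the implied template length is within [insert_min, insert_max]. Each hit
    joins at most one pair; candidates are taken by summed percent identity
    (ties: leftmost position). Returns (pairs, leftover1, leftover2).
    """
    candidates = []
    for a in hits1:
        for b in hits2:
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            left, right = (a, b) if a.ref_start <= b.ref_start else (b, a)
            if left.strand != "+":
                continue
            tlen = right.ref_end - left.ref_start
            if not (insert_min <= tlen <= insert_max):
                continue
            candidates.append((a, b))
    candidates.sort(key=lambda ab: (-(ab[0].s_exact + ab[1].s_exact),
                                    min(ab[0].ref_start, ab[1].ref_start)))
    used1: set[int] = set()
    used2: set[int] = set()
    pairs = []
    for a, b in candidates:
        if id(a) in used1 or id(b) in used2:
            continue
        pairs.append((a, b))
        used1.add(id(a))
        used2.add(id(b))
    left1 = [h for h in hits1 if id(h) not in used1]
    left2 = [h for h in hits2 if id(h) not in used2]
    return pairs, left1, left2


def _dp_matrix(read: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Unit-cost global edit DP matrix, rows vectorized with a prefix-min scan.

    The within-row dependency curr[j] = min(base[j], curr[j-1] + 1) is the
    running minimum of base[j] - j shifted back, so each row is a handful of
    array operations.
    """
    m, n = len(read), len(window)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = np.arange(n + 1, dtype=np.int32)
    cols = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        prev = D[i - 1]
        sub = prev[:-1] + (window != read[i - 1])
        base = np.minimum(prev[1:] + 1, sub)
        row = np.concatenate(([np.int32(i)], base))
        D[i] = np.minimum.accumulate(row - cols) + cols
    return D


def traceback_alignment(
    read_codes: np.ndarray,
    window_codes: np.ndarray,
    style: str = "semi-global",
) -> tuple[list[tuple[str, int]], int, int, int]:
    """CIGAR for the read aligned end-to-end against the validated span.

    Returns ``(cigar, nm, ref_offset, ref_len)``: run-length encoded CIGAR
    operations, the edit count along the path (== the validated k for
    semi-global style), and the used span of the window (local style may
    soft-clip read ends and shrink the span; clips are excluded from nm).
    """
    read = np.asarray(read_codes, dtype=np.uint8)
    window = np.asarray(window_codes, dtype=np.uint8)
    D = _dp_matrix(read, window)
    i, j = len(read), len(window)
    steps: list[tuple[str, bool]] = []  # (op, is_edit) per single step, reversed
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (read[i - 1] != window[j - 1]):
            steps.append(("M", bool(read[i - 1] != window[j - 1])))
            i -= 1
            j -= 1
        elif j > 0 and D[i, j] == D[i, j - 1] + 1:
            steps.append(("D", True))
            j -= 1
        else:
            steps.append(("I", True))
            i -= 1
    steps.reverse()

    lead_clip = trail_clip = 0
    ref_lo, ref_hi = 0, len(window)
    if style == "local":
        steps, lead_clip, trail_clip, ref_lo, ref_hi = _local_clip(steps, len(window))
    elif style != "semi-global":
        raise ValueError(f"unknown alignment style {style!r}")

    cigar: list[tuple[str, int]] = []
    if lead_clip:
        cigar.append(("S", lead_clip))
    for op, edit in steps:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    if trail_clip:
        cigar.append(("S", trail_clip))
    nm = sum(1 for op, edit in steps if edit)
    return cigar, nm, ref_lo, ref_hi - ref_lo


def _local_clip(steps: list[tuple[str, bool]], window_len: int):
    """Soft-clip read ends: keep the maximum-scoring contiguous path segment.

    Path steps score +1 for a match and -1 for any edit (Kadane's scan); if
    no positive-scoring segment exists the full path is kept.
    """
    best_sum = 0
    best_range = (0, len(steps))
    cur_sum = 0
    cur_start = 0
    found = False
    for idx, (op, edit) in enumerate(steps):
        gain = -1 if edit else 1
        if cur_sum <= 0:
            cur_sum = gain
            cur_start = idx
        else:
            cur_sum += gain
        if cur_sum > best_sum:
            best_sum = cur_sum
            best_range = (cur_start, idx + 1)
            found = True
    if not found:
        return steps, 0, 0, 0, window_len
    lo, hi = best_range
    # trim D ops at segment edges (they consume reference, not read)
    while lo < hi and steps[lo][0] == "D":
        lo += 1
    while hi > lo and steps[hi - 1][0] == "D":
        hi -= 1
    lead_clip = sum(1 for op, _ in steps[:lo] if op in "MI")
    trail_clip = sum(1 for op, _ in steps[hi:] if op in "MI")
    ref_lo = sum(1 for op, _ in steps[:lo] if op in "MD")
    ref_hi = window_len - sum(1 for op, _ in steps[hi:] if op in "MD")
    return steps[lo:hi], lead_clip, trail_clip, ref_lo, ref_hi


def cigar_to_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)
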