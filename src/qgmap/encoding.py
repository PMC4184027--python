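"""Two-bit DNA encoding, ambiguity handling and q-gram extraction.

DNA is packed as ``A=00, C=01, G=10, T=11`` so that a q-gram is a base-4
number ``g`` in ``[0, 4**q)`` whose most significant digit is the first base
— numeric order of ``g`` equals lexicographic order of the q-gram.

Ambiguous IUPAC letters are replaced uniformly at random among their
compatible bases (deterministically, given a seed); maximal runs of ``N`` of
at least ``n_run_threshold`` bases are additionally recorded as *skipped
runs* whose q-grams are never indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncodedSequence",
    "SequenceError",
    "encode_sequence",
    "encode_qgram",
    "qgram_codes",
    "indexable_positions",
    "reverse_complement",
    "codes_to_str",
]

_BASES = "ACGT"

# IUPAC letter -> tuple of compatible 2-bit codes. U is treated as T.
IUPAC_CODES: dict[str, tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3),
}

_AMBIGUOUS = "RYSWKMBDHVN"  # fixed order keeps seeded replacement reproducible

# 256-entry tables for vectorized translation
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _c in "ACGTU":
    _CODE_TABLE[ord(_c)] = IUPAC_CODES[_c][0]
_IUPAC_MASK = np.zeros(256, dtype=bool)
for _c in IUPAC_CODES:
    _IUPAC_MASK[ord(_c)] = True


class SequenceError(ValueError):
    """Raised for non-IUPAC input characters (the message names the position)."""


@dataclass
class EncodedSequence:
    """A 2-bit encoded DNA sequence with ambiguity bookkeeping.

    Attributes
    ----------
    codes : np.ndarray of uint8
        One entry per base, each in {0, 1, 2, 3}.
    n_mask : np.ndarray of int64
        Sorted positions whose original base was ambiguous and was replaced.
    skipped_runs : list of (start, end)
        Disjoint, sorted half-open intervals of long N runs; q-grams
        overlapping them are never indexed. A zero-length interval (x, x)
        acts as a cut point: windows may touch but not cross x.
    """

    codes: np.ndarray
    n_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    skipped_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def decode(self) -> str:
        """Back to letters (replaced ambiguous positions decode to the drawn base)."""
        return codes_to_str(self.codes)


def codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def encode_sequence(raw: str, rng_seed: int = 0, n_run_threshold: int = 10) -> EncodedSequence:
    """Encode an IUPAC DNA string into 2-bit codes.

    Ambiguous letters are replaced uniformly at random among their compatible
    bases; the replacement is deterministic for a fixed ``rng_seed``.
    Maximal runs of ``N`` with length >= ``n_run_threshold`` are recorded in
    ``skipped_runs`` so they are excluded from indexing.
    """
    arr = np.frombuffer(raw.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    if arr.size == 0:
        return EncodedSequence(np.empty(0, dtype=np.uint8))
    bad = ~_IUPAC_MASK[arr]
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise SequenceError(f"non-IUPAC character {raw[pos]!r} at position {pos}")
    codes = _CODE_TABLE[arr].copy()
    ambiguous = codes == 255
    n_mask = np.flatnonzero(ambiguous).astype(np.int64)
    if n_mask.size:
        rng = np.random.default_rng(rng_seed)
        for letter in _AMBIGUOUS:
            where = np.flatnonzero(arr == ord(letter))
            if where.size:
                choices = np.array(IUPAC_CODES[letter], dtype=np.uint8)
                codes[where] = choices[rng.integers(0, len(choices), size=where.size)]
    runs = _n_runs(arr, n_run_threshold)
    return EncodedSequence(codes, n_mask, runs)


def _n_runs(arr: np.ndarray, threshold: int) -> list[tuple[int, int]]:
    """Maximal runs of 'N' with length >= threshold, as half-open intervals."""
    is_n = arr == ord("N")
    if not is_n.any():
        return []
    padded = np.concatenate(([False], is_n, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= threshold]


def qgram_codes(codes: np.ndarray, q: int) -> np.ndarray:
    """Numeric codes of every q-gram window, as uint64 (length ``L - q + 1``).

    Position ``p`` holds the base-4 value of ``codes[p:p+q]`` with the first
    base most significant.
    """
    codes = np.asarray(codes, dtype=np.uint64)
    n = codes.shape[0] - q + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    g = np.zeros(n, dtype=np.uint64)
    for t in range(q):
        g |= codes[t : t + n] << np.uint64(2 * (q - 1 - t))
    return g


def indexable_positions(seq: EncodedSequence, q: int) -> np.ndarray:
    """Start positions admitting a full q-gram that avoids every skipped run."""
    n = len(seq) - q + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for a, b in seq.skipped_runs:
        lo = max(0, a - q + 1)
        hi = min(b, n)
        if lo < hi:
            valid[lo:hi] = False
    return np.flatnonzero(valid).astype(np.int64)


def encode_qgram(seq: "EncodedSequence | np.ndarray", offset: int, q: int) -> int | None:
    """Numeric code of the q-gram at ``offset``; None when it overlaps a skipped run."""
    if isinstance(seq, EncodedSequence):
        codes = seq.codes
        for a, b in seq.skipped_runs:
            if offset < b and offset + q > a:
                return None
    else:
        codes = np.asarray(seq, dtype=np.uint8)
    if offset < 0 or offset + q > codes.shape[0]:
        raise ValueError(f"q-gram window [{offset}, {offset + q}) out of bounds")
    g = 0
    for c in codes[offset : offset + q]:
        g = (g << 2) | int(c)
    return g


def reverse_complement(seq: EncodedSequence) -> EncodedSequence:
    """Reverse complement: code ``x`` maps to ``3 - x``, order reversed."""
    n = len(seq)
    codes = (3 - seq.codes)[::-1].copy()
    n_mask = np.sort(n - 1 - seq.n_mask) if seq.n_mask.size else seq.n_mask
    runs = sorted((n - b, n - a) for a, b in seq.skipped_runs)
    return EncodedSequence(codes, n_mask.astype(np.int64), runs)
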