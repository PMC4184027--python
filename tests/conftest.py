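"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (full DP tables, exhaustive scans)
and independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest


def dp_semiglobal(read, window) -> int:
    """Unbanded semi-global Levenshtein: read global, window substring free."""
    m, n = len(read), len(window)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (read[i - 1] != window[j - 1]))
        prev = cur
    return min(prev)


def dp_global(read, window) -> int:
    """Plain global Levenshtein distance."""
    m, n = len(read), len(window)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (read[i - 1] != window[j - 1]))
        prev = cur
    return prev[n]


def random_codes(rng, n) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.uint8)


def mutate(rng, codes, n_subs=0, n_ins=0, n_del=0) -> np.ndarray:
    """Apply random edits to a copy of ``codes`` (substitutions always change)."""
    out = list(codes)
    for _ in range(n_del):
        if len(out) > 1:
            del out[int(rng.integers(0, len(out)))]
    for _ in range(n_ins):
        out.insert(int(rng.integers(0, len(out) + 1)), int(rng.integers(0, 4)))
    for _ in range(n_subs):
        at = int(rng.integers(0, len(out)))
        out[at] = (out[at] + int(rng.integers(1, 4))) % 4
    return np.array(out, dtype=np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
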