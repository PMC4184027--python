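"""Build a q-group index over a small text and look up q-gram occurrences.

The index is the four-array structure (I, S, S', O): a per-group occurrence
bit mask, its cumulative popcounts, per-q-gram offsets, and the occurrence
positions. Lookup is one division, one masked popcount and two array reads.
"""

import numpy as np

from qgmap import build, indexpair, positions
from qgmap.encoding import encode_qgram, encode_sequence

text = encode_sequence("ACGTACGTTTACGT")
idx = build(text, q=4)

print(f"text length {len(text)}, distinct 4-grams: {idx.n_distinct}, "
      f"|O| = {idx.O.size}")
for gram in ("ACGT", "CGTA", "TTTT"):
    g = encode_qgram(encode_sequence(gram), 0, 4)
    pair = indexpair(idx, g)
    pos = sorted(positions(idx, g).tolist())
    print(f"{gram} (g={g:3d}): interval {pair}, positions {pos}")
# ACGT occurs at 0, 4 and 10; TTTT never occurs, so its interval is absent.
print("words used:", idx.total_words())
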