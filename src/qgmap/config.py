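"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Tunable parameters of a mapping run.

    Defaults: q=16 (a 2-bit 16-mer fills a 32-bit word and gives good
    specificity with useful error tolerance), identity threshold 80%,
    best-stratum reporting, likelihood decay lambda=1 with scale C=1, and a
    mapping-quality cap of 60.
    """

    q: int = 16
    w: int = 32
    identity_threshold: float = 80.0
    mode: str = "best-stratum"          # or "all"
    lam: float = 1.0
    likelihood_const: float = 1.0
    mapq_cap: int = 60
    buffer_size: int = 100_000          # reads per batch
    absolute_cap: int = 1000            # frequent-q-gram masking: absolute count
    frequency_cap: float = 1e-4         # ... and per-chromosome frequency
    masking: bool = True
    insert_min: int = 0
    insert_max: int = 1000
    delta: int = 3                      # diagonal merge distance
    band_width: int = 32
    seed: int = 0
    threads: int = 1
    alignment_style: str = "semi-global"  # or "local"
    n_run_threshold: int = 10

    def validate(self) -> None:
        if self.mode not in ("all", "best-stratum"):
            raise ValueError(f"mode must be 'all' or 'best-stratum', got {self.mode!r}")
        if self.alignment_style not in ("semi-global", "local"):
            raise ValueError(f"unknown alignment style {self.alignment_style!r}")
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if 2 * self.q > self.w:
            raise ValueError(f"q={self.q} does not fit word size w={self.w}")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)
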