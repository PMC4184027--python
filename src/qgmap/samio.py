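"""FASTQ input and SAM 1.x text output."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = ["SamRecord", "read_fastq", "sam_header", "FLAG_PAIRED",
           "FLAG_PROPER", "FLAG_UNMAPPED", "FLAG_MATE_UNMAPPED",
           "FLAG_REVERSE", "FLAG_MATE_REVERSE", "FLAG_READ1", "FLAG_READ2",
           "FLAG_SECONDARY"]

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100


def read_fastq(path: str | Path):
    """Yield (name, sequence, quality-string) from a FASTQ file (.gz ok)."""
    path = str(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), qual
    finally:
        handle.close()


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0          # 1-based; 0 for unmapped
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: list[str] = field(default_factory=list)

    def to_line(self) -> str:
        fields = [self.qname, str(self.flag), self.rname, str(self.pos),
                  str(self.mapq), self.cigar, self.rnext, str(self.pnext),
                  str(self.tlen), self.seq, self.qual, *self.tags]
        return "\t".join(fields)


def sam_header(references: list[tuple[str, int]], pg_args: str) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@PG\tID:qgmap\tPN:qgmap\tCL:{pg_args}")
    return lines
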