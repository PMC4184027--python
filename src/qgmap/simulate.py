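"""Synthetic genomes, reads with planted errors, and truth-based evaluation.

The generator emulates a short-read resequencing experiment at its
defaults: a uniform i.i.d. random genome (no repeat structure unless
explicitly injected), 100 bp reads drawn uniformly over positions and
strands, and per-read planted substitutions/indels with recorded counts so
every mapping can be judged against its known origin. Metrics follow the
conventions of simulation benchmarks: a hit is *correct* when chromosome
and strand match and the reported start is within ``tolerance_bp`` (default
5) of the true origin; sensitivity asks whether any reported hit is
correct, recall whether the primary hit is, precision how many of the
unambiguously mapped reads are correct.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

__all__ = ["ReadTruth", "simulate_genome", "inject_repeat", "simulate_reads",
           "evaluate", "write_truth", "read_truth", "write_fasta", "write_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ReadTruth:
    name: str
    chrom: str
    strand: str
    start: int          # 0-based forward-strand start of the origin window
    n_subs: int
    n_ins: int
    n_del: int

    @property
    def edits(self) -> int:
        return self.n_subs + self.n_ins + self.n_del


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def simulate_genome(length: int, seed: int = 0) -> str:
    """Uniform i.i.d. ACGT sequence; deterministic per seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def inject_repeat(genome: str, segment_start: int, segment_len: int, copies: int,
                  seed: int = 0) -> str:
    """Copy one segment to ``copies`` random non-overlapping loci.

    Exercises ambiguity handling: reads from the repeat should map with
    quality 0.
    """
    rng = np.random.default_rng(seed)
    segment = genome[segment_start : segment_start + segment_len]
    out = list(genome)
    for _ in range(copies):
        at = int(rng.integers(0, len(genome) - segment_len + 1))
        out[at : at + segment_len] = segment
    return "".join(out)


def simulate_reads(
    genome: "str | list[tuple[str, str]]",
    n_reads: int,
    read_len: int = 100,
    max_subs: int = 0,
    max_indels: int = 0,
    indel_max_len: int = 1,
    paired: bool = False,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[ReadTruth]]:
    """Sample reads with planted errors; return (reads, truth).

    Each read draws a uniform origin and strand; its substitution count is
    uniform on {0..max_subs} (always to a different base, so planted counts
    are effective) and its indel count uniform on {0..max_indels} with
    lengths in {1..indel_max_len}. Paired mode emits FR mates around a
    normal fragment length. Reads are (name, sequence, quality) triples.
    """
    chroms = [("chr1", genome)] if isinstance(genome, str) else list(genome)
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    truth: list[ReadTruth] = []

    def one_read(name: str, chrom_name: str, seq: str, start: int, strand: str):
        n_subs = int(rng.integers(0, max_subs + 1))
        n_ind = int(rng.integers(0, max_indels + 1)) if max_indels else 0
        window = list(seq[start : start + read_len + n_ind * indel_max_len])
        n_ins = n_del = 0
        for _ in range(n_ind):
            ln = int(rng.integers(1, indel_max_len + 1))
            if rng.random() < 0.5 and len(window) > read_len + ln:
                at = int(rng.integers(0, len(window) - ln))
                del window[at : at + ln]
                n_del += ln
            else:
                at = int(rng.integers(0, len(window) + 1))
                ins = _BASES[rng.integers(0, 4, size=ln)].tobytes().decode()
                window[at:at] = list(ins)
                n_ins += ln
        window = window[:read_len]
        if n_subs:
            sites = rng.choice(read_len, size=min(n_subs, read_len), replace=False)
            for at in sites:
                old = window[at]
                alt = "ACGT".replace(old, "")
                window[at] = alt[int(rng.integers(0, 3))]
            n_subs = len(sites)
        read_seq = "".join(window)
        if strand == "-":
            read_seq = _revcomp(read_seq)
        reads.append((name, read_seq, "I" * read_len))
        truth.append(ReadTruth(name, chrom_name, strand, start, n_subs, n_ins, n_del))

    weights = np.array([max(len(s) - read_len + 1, 0) for _, s in chroms], dtype=float)
    if weights.sum() == 0:
        raise ValueError(f"no chromosome admits reads of length {read_len}")
    weights /= weights.sum()

    for i in range(n_reads):
        ci = int(rng.choice(len(chroms), p=weights))
        cname, cseq = chroms[ci]
        if not paired:
            start = int(rng.integers(0, len(cseq) - read_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            one_read(f"read{i}", cname, cseq, start, strand)
        else:
            frag = max(read_len, int(round(rng.normal(insert_mean, insert_sd))))
            frag = min(frag, len(cseq))
            fstart = int(rng.integers(0, len(cseq) - frag + 1))
            one_read(f"read{i}/1", cname, cseq, fstart, "+")
            one_read(f"read{i}/2", cname, cseq, fstart + frag - read_len, "-")
    return reads, truth


def evaluate(
    sam_path: str | Path,
    truth: list[ReadTruth],
    tolerance_bp: int = 5,
) -> dict[str, float]:
    """Sensitivity, recall and precision of a SAM file against the truth.

    Correct hit: same chromosome and strand, |reported start - true start|
    <= tolerance_bp. Sensitivity counts reads with any correct reported hit;
    recall counts reads whose primary hit is correct; precision is the
    fraction of correct reads among reads mapped unambiguously (exactly one
    reported hit).
    """
    by_name = {t.name: t for t in truth}
    hits: dict[str, list[tuple[str, str, int, bool]]] = {t.name: [] for t in truth}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            name = rec.query_name
            if rec.is_paired:
                name = f"{name}/{1 if rec.is_read1 else 2}"
            if name not in by_name:
                raise ValueError(f"SAM read name {name!r} not present in truth")
            strand = "-" if rec.is_reverse else "+"
            hits[name].append((rec.reference_name, strand, rec.reference_start,
                               not rec.is_secondary))
    n = len(truth)
    found = 0
    primary_correct = 0
    unambiguous = 0
    unambiguous_correct = 0
    for t in truth:
        recs = hits[t.name]
        correct = [
            (chrom == t.chrom and strand == t.strand and abs(pos - t.start) <= tolerance_bp)
            for chrom, strand, pos, _ in recs
        ]
        if any(correct):
            found += 1
        prim = [ok for (c, s, p, is_p), ok in zip(recs, correct) if is_p]
        if prim and prim[0]:
            primary_correct += 1
        if len(recs) == 1:
            unambiguous += 1
            if correct[0]:
                unambiguous_correct += 1
    return {
        "sensitivity": found / n if n else 0.0,
        "recall": primary_correct / n if n else 0.0,
        "precision": (unambiguous_correct / unambiguous) if unambiguous else 0.0,
        "n_reads": float(n),
    }


_TRUTH_FIELDS = ["name", "chrom", "strand", "start", "n_subs", "n_ins", "n_del"]


def write_truth(truth: list[ReadTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TRUTH_FIELDS)
        for t in truth:
            w.writerow([t.name, t.chrom, t.strand, t.start, t.n_subs, t.n_ins, t.n_del])


def read_truth(path: str | Path) -> list[ReadTruth]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(ReadTruth(row["name"], row["chrom"], row["strand"],
                                 int(row["start"]), int(row["n_subs"]),
                                 int(row["n_ins"]), int(row["n_del"])))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
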