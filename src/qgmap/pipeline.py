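"""End-to-end mapping pipeline: batches -> filtration -> validation -> SAM.

The stage decomposition mirrors the filtration / validation / postprocessing
split: per read batch a q-group index is built over the concatenated reads,
every chromosome is streamed against it on both strands (the minus strand
via the reverse-complemented reference, with coordinates folded back), the
surviving hits are stratified and annotated, and records are emitted in
input read order. Everything is deterministic for a fixed seed and
configuration — reruns produce a byte-identical SAM body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import RunConfig
from .encoding import encode_sequence
from .filtration import ReadBatch, ReadRecord, generate_hits, make_batches
from .postprocess import (
    MappingQualityModel,
    build_strata,
    cigar_to_string,
    mapping_quality,
    pair_mates,
    traceback_alignment,
)
from .qgroup import build as build_qgroup
from .refindex import ChromosomeIndex, ReferenceIndex
from .samio import (
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    SamRecord,
    sam_header,
)
from .validation import ValidatedHit, dedup_validated, validate_hits

__all__ = ["MappingStats", "map_reads", "sam_lines"]

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class MappingStats:
    reads: int = 0
    skipped_short: int = 0
    candidates: int = 0
    validated: int = 0
    reported: int = 0
    unmapped: int = 0
    batches: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _to_records(reads1, reads2, config: RunConfig) -> list[ReadRecord]:
    """Encode the input reads; mates are interleaved so pairs share a batch."""
    records: list[ReadRecord] = []

    def add(name, seq, qual, mate, pair_id, i):
        enc = encode_sequence(seq, rng_seed=(config.seed * 2_654_435 + i) % (2**31),
                              n_run_threshold=config.n_run_threshold)
        records.append(ReadRecord(name=name, seq=enc, qual=qual, mate=mate,
                                  pair_id=pair_id, raw_seq=seq))

    if reads2 is None:
        for i, (name, seq, qual) in enumerate(reads1):
            add(name, seq, qual, 0, -1, i)
    else:
        reads1, reads2 = list(reads1), list(reads2)
        if len(reads1) != len(reads2):
            raise ValueError(
                f"paired FASTQ files differ in read count: {len(reads1)} vs {len(reads2)}"
            )
        for i, (r1, r2) in enumerate(zip(reads1, reads2)):
            add(*r1, 1, i, 2 * i)
            add(*r2, 2, i, 2 * i + 1)
    return records


def _batch_hits(batch: ReadBatch, ref: ReferenceIndex, config: RunConfig,
                stats: MappingStats) -> list[list[ValidatedHit]]:
    """Filtration + validation for one batch; hits in forward coordinates."""
    bindex = build_qgroup(batch.concat, ref.q, config.w)
    per_read: list[list[ValidatedHit]] = [[] for _ in range(batch.count)]
    for chrom in ref.chromosomes:
        for strand in "+-":
            if strand == "+":
                stream_g, stream_p, seq = chrom.p_gram, chrom.p_pos, chrom.seq
            else:
                stream_g, stream_p, seq = chrom.p_gram_rc, chrom.p_pos_rc, chrom.rc_seq
            cand = generate_hits(bindex, batch, stream_g, stream_p,
                                 delta=config.delta, q=ref.q)
            stats.candidates += int(cand[0].size)
            hits = validate_hits(cand, batch, seq, chrom.name, strand,
                                 identity_threshold=config.identity_threshold,
                                 band_width=config.band_width)
            if strand == "-":
                L = chrom.length
                for h in hits:
                    h.ref_start, h.ref_end = L - h.ref_end, L - h.ref_start
            for h in hits:
                per_read[h.read_id].append(h)
    flat = dedup_validated([h for hs in per_read for h in hs])
    deduped: list[list[ValidatedHit]] = [[] for _ in range(batch.count)]
    for h in flat:
        deduped[h.read_id].append(h)
    stats.validated += len(flat)
    return deduped


def _alignment_fields(hit: ValidatedHit, batch: ReadBatch,
                      chrom: ChromosomeIndex, style: str):
    """CIGAR, NM, 1-based POS, oriented SEQ/QUAL and 0-based excl. end."""
    rec = batch.records[hit.read_id]
    read_codes = rec.seq.codes
    L = chrom.length
    if hit.strand == "+":
        window = chrom.seq.codes[hit.ref_start:hit.ref_end]
        cigar, nm, off, used = traceback_alignment(read_codes, window, style=style)
        pos0 = hit.ref_start + off
        seq, qual = rec.raw_seq.upper(), rec.qual
    else:
        rc_lo, rc_hi = L - hit.ref_end, L - hit.ref_start
        window = chrom.rc_seq.codes[rc_lo:rc_hi]
        cigar, nm, off, used = traceback_alignment(read_codes, window, style=style)
        pos0 = L - (rc_lo + off + used)
        cigar = cigar[::-1]
        seq, qual = _revcomp(rec.raw_seq.upper()), rec.qual[::-1]
    if style == "semi-global" and nm != hit.k:
        raise AssertionError(
            f"traceback edit count {nm} != validated distance {hit.k} "
            f"(read {hit.read_id} @ {hit.chrom}:{hit.ref_start})"
        )
    return cigar_to_string(cigar), nm, pos0 + 1, seq, qual, pos0 + used


def map_reads(ref: ReferenceIndex, reads1, reads2=None,
              config: RunConfig | None = None):
    """Map reads against a reference index.

    ``reads1``/``reads2`` are iterables of (name, sequence, quality) tuples
    (``reads2`` switches on paired-end mode). Returns ``(records, stats)``
    where records is the list of SamRecord in deterministic output order.
    """
    config = config or RunConfig()
    config.validate()
    if config.q != ref.q:
        raise ValueError(f"config q={config.q} does not match reference index q={ref.q}")
    stats = MappingStats()
    model = MappingQualityModel(lam=config.lam, const=config.likelihood_const,
                                cap=config.mapq_cap)
    chrom_by_name = {c.name: c for c in ref.chromosomes}
    chrom_order = {c.name: i for i, c in enumerate(ref.chromosomes)}
    records = _to_records(reads1, reads2, config)
    paired = reads2 is not None
    out: list[SamRecord] = []

    buffer_reads = config.buffer_size * (2 if paired else 1)
    gen = make_batches(iter(records), ref.q, buffer_reads)
    while True:
        try:
            batch = next(gen)
        except StopIteration as stop:
            stats.skipped_short = stop.value or 0
            break
        stats.batches += 1
        stats.reads += batch.count
        hits = _batch_hits(batch, ref, config, stats)
        if paired:
            out.extend(_report_paired(batch, hits, chrom_by_name, chrom_order,
                                      model, config, stats))
        else:
            out.extend(_report_single(batch, hits, chrom_by_name, chrom_order,
                                      model, config, stats))
        log.info("batch %d: %d reads, %d candidates, %d validated, %d reported",
                 stats.batches, batch.count, stats.candidates, stats.validated,
                 stats.reported)
    return out, stats


def _hit_key(chrom_order, h: ValidatedHit):
    return (chrom_order[h.chrom], h.ref_start, 0 if h.strand == "+" else 1)


def _report_single(batch, hits, chrom_by_name, chrom_order, model,
                   config: RunConfig, stats: MappingStats):
    out = []
    for rid, rec in enumerate(batch.records):
        read_hits = hits[rid]
        if not read_hits:
            stats.unmapped += 1
            out.append(SamRecord(qname=rec.name, flag=FLAG_UNMAPPED,
                                 seq=rec.raw_seq.upper(), qual=rec.qual))
            continue
        quals = dict(zip(map(id, read_hits), mapping_quality(read_hits, model)))
        first = True
        for stratum in build_strata(read_hits, mode=config.mode):
            for h in sorted(stratum.hits, key=lambda x: _hit_key(chrom_order, x)):
                chrom = chrom_by_name[h.chrom]
                cigar, nm, pos, seq, qual, _ = _alignment_fields(
                    h, batch, chrom, config.alignment_style)
                flag = 0 if h.strand == "+" else FLAG_REVERSE
                if not first:
                    flag |= FLAG_SECONDARY
                out.append(SamRecord(
                    qname=rec.name, flag=flag, rname=h.chrom, pos=pos,
                    mapq=quals[id(h)], cigar=cigar, seq=seq, qual=qual,
                    tags=[f"NM:i:{nm}", f"AS:i:{round(h.s)}", f"XR:i:{stratum.rank}"],
                ))
                stats.reported += 1
                first = False
    return out


def _paired_entities(pairs, pair_scores, left1, left2, mode):
    """Stratified entities: proper pairs by summed identity, then singletons.

    Returns a list of strata; each stratum is a list of entities, either
    ("pair", hit1, hit2) or ("single", mate_no, hit). In best-stratum mode
    only the top stratum survives (pairs outrank all singletons).
    """
    from collections import defaultdict

    pair_strata = defaultdict(list)
    for (a, b), s in zip(pairs, pair_scores):
        pair_strata[s].append(("pair", a, b))
    ordered = [pair_strata[s] for s in sorted(pair_strata, reverse=True)]
    single_strata = defaultdict(list)
    for mate_no, leftovers in ((1, left1), (2, left2)):
        for h in leftovers:
            single_strata[h.s_exact].append(("single", mate_no, h))
    singles = [single_strata[s] for s in sorted(single_strata, reverse=True)]
    if mode == "best-stratum":
        return ordered[:1] if ordered else singles[:1]
    return ordered + singles


def _report_paired(batch, hits, chrom_by_name, chrom_order, model,
                   config: RunConfig, stats: MappingStats):
    out = []
    by_pair: dict[int, dict[int, int]] = {}
    for rid, rec in enumerate(batch.records):
        by_pair.setdefault(rec.pair_id, {})[rec.mate] = rid
    for pair_id in sorted(by_pair):
        mates = by_pair[pair_id]
        rid = {1: mates.get(1), 2: mates.get(2)}
        h1 = hits[rid[1]] if rid[1] is not None else []
        h2 = hits[rid[2]] if rid[2] is not None else []
        pairs, left1, left2 = pair_mates(h1, h2, config.insert_min, config.insert_max)
        pair_scores = [a.s_exact + b.s_exact for a, b in pairs]
        forced = None
        if pair_scores:
            best = max(pair_scores)
            if sum(1 for s in pair_scores if s == best) >= 2:
                forced = True
        qmap = {
            1: dict(zip(map(id, h1), mapping_quality(h1, model, ambiguous_best=forced))),
            2: dict(zip(map(id, h2), mapping_quality(h2, model, ambiguous_best=forced))),
        }
        strata = _paired_entities(pairs, pair_scores, left1, left2, config.mode)

        mate_mapped = {1: False, 2: False}
        for stratum in strata:
            for ent in stratum:
                if ent[0] == "pair":
                    mate_mapped[1] = mate_mapped[2] = True
                else:
                    mate_mapped[ent[1]] = True

        def ent_pos(e):
            if e[0] == "pair":
                return (min(_hit_key(chrom_order, e[1]), _hit_key(chrom_order, e[2])), 0)
            return (_hit_key(chrom_order, e[2]), e[1])

        primary_done = {1: False, 2: False}
        first_pos = {1: None, 2: None}  # (rname, pos) of each mate's primary
        buffered = []
        for rank, stratum in enumerate(strata):
            for ent in sorted(stratum, key=ent_pos):
                if ent[0] == "pair":
                    _, a, b = ent
                    fa = _alignment_fields(a, batch, chrom_by_name[a.chrom],
                                           config.alignment_style)
                    fb = _alignment_fields(b, batch, chrom_by_name[b.chrom],
                                           config.alignment_style)
                    lo0 = min(fa[2], fb[2]) - 1
                    hi0 = max(fa[5], fb[5])
                    tlen = hi0 - lo0
                    for mate_no, h, f, other, otlen in ((1, a, fa, b, tlen),
                                                        (2, b, fb, a, -tlen)):
                        cig, nm, pos, seq, qual, _end = f
                        if (mate_no == 2) == (fa[2] <= fb[2]):
                            otlen = -abs(tlen)
                        else:
                            otlen = abs(tlen)
                        flag = FLAG_PAIRED | FLAG_PROPER
                        flag |= FLAG_READ1 if mate_no == 1 else FLAG_READ2
                        if h.strand == "-":
                            flag |= FLAG_REVERSE
                        if other.strand == "-":
                            flag |= FLAG_MATE_REVERSE
                        if primary_done[mate_no]:
                            flag |= FLAG_SECONDARY
                        else:
                            first_pos[mate_no] = (h.chrom, pos)
                        primary_done[mate_no] = True
                        opos = fb[2] if mate_no == 1 else fa[2]
                        buffered.append((SamRecord(
                            qname=_qname(batch.records[rid[mate_no]].name),
                            flag=flag, rname=h.chrom, pos=pos, mapq=qmap[mate_no][id(h)],
                            cigar=cig, rnext="=", pnext=opos, tlen=otlen,
                            seq=seq, qual=qual,
                            tags=[f"NM:i:{nm}", f"AS:i:{round(h.s)}", f"XR:i:{rank}"]),
                            mate_no))
                        stats.reported += 1
                else:
                    _, mate_no, h = ent
                    cig, nm, pos, seq, qual, _end = _alignment_fields(
                        h, batch, chrom_by_name[h.chrom], config.alignment_style)
                    flag = FLAG_PAIRED
                    flag |= FLAG_READ1 if mate_no == 1 else FLAG_READ2
                    if h.strand == "-":
                        flag |= FLAG_REVERSE
                    if not mate_mapped[3 - mate_no]:
                        flag |= FLAG_MATE_UNMAPPED
                    if primary_done[mate_no]:
                        flag |= FLAG_SECONDARY
                    else:
                        first_pos[mate_no] = (h.chrom, pos)
                    primary_done[mate_no] = True
                    buffered.append((SamRecord(
                        qname=_qname(batch.records[rid[mate_no]].name),
                        flag=flag, rname=h.chrom, pos=pos, mapq=qmap[mate_no][id(h)],
                        cigar=cig, seq=seq, qual=qual,
                        tags=[f"NM:i:{nm}", f"AS:i:{round(h.s)}", f"XR:i:{rank}"]),
                        mate_no))
                    stats.reported += 1
        # point singleton records at the mate's primary locus where known
        for rec_out, mate_no in buffered:
            other = first_pos[3 - mate_no]
            if rec_out.rnext == "*" and other is not None and not rec_out.flag & FLAG_UNMAPPED:
                rec_out.rnext = "=" if other[0] == rec_out.rname else other[0]
                rec_out.pnext = other[1]
        out.extend(r for r, _ in buffered)
        # fully unmapped mates
        for mate_no in (1, 2):
            if rid[mate_no] is None or primary_done[mate_no]:
                continue
            stats.unmapped += 1
            rec = batch.records[rid[mate_no]]
            flag = FLAG_PAIRED | FLAG_UNMAPPED
            flag |= FLAG_READ1 if mate_no == 1 else FLAG_READ2
            if not mate_mapped[3 - mate_no]:
                flag |= FLAG_MATE_UNMAPPED
            other = first_pos[3 - mate_no]
            rec_out = SamRecord(qname=_qname(rec.name), flag=flag,
                                seq=rec.raw_seq.upper(), qual=rec.qual)
            if other is not None:
                rec_out.rnext, rec_out.pnext = other[0], other[1]
            out.append(rec_out)
    return out


def _qname(name: str) -> str:
    return name.rsplit("/", 1)[0] if name.endswith(("/1", "/2")) else name


def sam_lines(ref: ReferenceIndex, records: list[SamRecord], config: RunConfig) -> list[str]:
    """Full SAM document (header + body), one string per line."""
    header = sam_header([(c.name, c.length) for c in ref.chromosomes],
                        pg_args=config.to_json())
    return header + [r.to_line() for r in records]
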