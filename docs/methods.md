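# Methods

## The q-group index

A classical q-gram index keeps an address table of `4^q` integers plus a
position table of `|T|` integers. The q-group index replaces the address
table with (i) one bit per possible q-gram, packed into `w`-bit group
words (`I`), (ii) the cumulative popcounts of those words (`S`), and
(iii) one offset per *occurring* q-gram (`S′`). The position table `O` is
unchanged in size. Querying q-gram `g` computes the group `i = ⌊g/w⌋` and
bit `j = g mod w`, tests bit `j` of `I[i]`, computes the in-group rank
`j′ = Popcount(I[i] & (2^j − 1))`, and reads the half-open interval
`[S′[S[i]+j′], S′[S[i]+j′+1])` of `O` — constant time per reported
position.

Construction is a sequence of whole-array passes: occurring q-gram codes
are collected, `I` is assembled from them, `S` and `S′` are cumulative
sums (popcounts of `I`; per-q-gram occurrence counts), and positions are
placed into their intervals of `O`. In this implementation the passes are
vectorized numpy operations; a sort by q-gram code realizes the
grouping. The *order* of positions inside one q-gram's interval is
deliberately unspecified (set-level contract); the serializer sorts each
interval so on-disk artifacts are canonical. `S` carries a terminal
sentinel entry for uniform interval access, and an optional half-sampled
variant stores only even entries of `S`, reconstructing odd ones with one
extra popcount per query.

Word size is fixed to `w = 32` by default (`w = 64` available;
`2q ≤ w` enforced). Building at `q = 16` allocates the full
`⌈4^16/32⌉`-word `I` and `S` (~1 GiB together); this is the intended
operating point for batch-indexed reads.

## Encoding and ambiguity

Bases pack as `A=00, C=01, G=10, T=11`, first base most significant, so
numeric q-gram order equals lexicographic order. Ambiguous IUPAC letters
are replaced uniformly at random among their compatible bases; the
replacement is seeded from one run-level seed and recorded per position.
Maximal runs of `N` of at least `n_run_threshold` bases (default 10; the
threshold is configurable since no canonical value exists) become
*skipped runs* excluded from indexing. Zero-length skipped intervals act
as cut points — windows may touch but not cross them — which is how read
concatenation prevents q-grams from spanning two reads even when a read
fills its slot exactly.

## Filtration

Reads are buffered into batches (default 100,000; the mapping semantics
do not depend on the batch size) and concatenated into fixed-length slots
of the batch's maximum read length, so the read number of an index hit is
an integer division. The *reference* is streamed against the batch index:
for each chromosome, a precomputed stream `P` of `(q-gram, position)`
pairs sorted by numeric code (stability keeps positions ascending within
a code) is probed; each occurrence `o` yields the candidate diagonal
`p − (o mod slot)`. The per-position counts, an exclusive prefix sum and
a compaction pass preserve the count/scan/scatter structure of the
parallel formulation (the output length equals the count sum); here they
are numpy passes rather than device kernels — the semantics, not the
hardware mapping, are the contract. Exceedingly frequent q-grams are
masked from `P` at build time; since no canonical cutoff exists, the
threshold is `max(absolute_cap, ⌈frequency_cap · chromosome length⌉)`
per chromosome (defaults 1000 and 1e-4), both exposed on the CLI, and
masking can be disabled.

Strand handling: each chromosome contributes a second stream built from
its reverse complement, so one read-batch index serves both strands;
minus-strand coordinates are folded back to forward coordinates after
validation (`start, end → L − end, L − start`). Candidate diagonals are
deduplicated per (read, strand, chromosome) and nearby diagonals within
`±Δ` (default 3) merge to the smallest representative, tolerating small
indel-induced seed shifts; negative diagonals clamp to 0, the validation
window absorbing the overhang.

With reads of length `n` and `e < (n+1)/q − 1` errors, the pigeonhole
principle guarantees a shared q-gram, hence the true diagonal survives
filtration (tested at `n = 100, q = 16`, `e ≤ 5`).

## Validation

Each candidate expands to the reference window
`[diagonal − pad, diagonal + |r| + pad]`, `pad = band_width/2` (default
band 32; the symmetric slack is a documented choice — no canonical window
formula exists). The window extent is what realizes the diagonal band:
any path inside it deviates at most `pad` columns from the candidate
diagonal, bounding insertion/deletion size while leaving mismatches
unaffected; larger indels can only surface as partial (soft-clipped)
matches of the semi-global score, not as split alignments. The distance
is computed with the bit-parallel Myers column recurrence (vertical
deltas in two bit vectors, constant word work per reference column, zero
carry into the horizontal delta for the free reference start). Python
arbitrary-precision integers hold the bit vectors, i.e., the multi-word
blocked variant of the single-word recurrence: read length is not capped,
semantics are identical. A second pass on the reversed read against the
reversed window prefix locates the best start; ties resolve toward the
smallest start (forward pass: smallest end). Percent identity
`s = 100·(|r|−k)/|r|` is compared against the threshold (default 80) in
exact integer arithmetic (`100(|r|−k) ≥ thr·|r|`).

## Postprocessing

Strata group a read's hits by exact rational identity `(|r|−k)/|r|`
(cross-multiplied integers; no float equality). Reporting keeps all
strata or only the best. In paired mode, proper pairs — same chromosome,
forward–reverse orientation, template length within
`[insert_min, insert_max]` (defaults 0–1000; the canonical limits are a
matter of library preparation, so they are plain parameters) — are
formed greedily by summed identity and outrank all singleton hits.

Mapping quality: likelihood `L_p = C·e^{−λ(100−s_p)}` (defaults
`λ = C = 1`), posterior `L_p/ΣL` over the read's validated hits
(discarded hits are treated as zero likelihood, which the exponential
decay justifies), PHRED-scaled with *floor* rounding (conservative;
rounding mode is otherwise arbitrary), capped at 60 (posterior 1 maps
directly to the cap), and forced to 0 for all hits tied at the best
identity. In paired mode the ambiguity rule triggers at pair-score level:
if two or more proper pairs tie at the best summed identity, the mates'
tied hits report 0; likelihoods remain per read.

Alignments are recovered by a unit-cost DP traceback over the validated
span (row-vectorized fill, diagonal-preferring tie-break, so CIGARs are
deterministic); for semi-global style the CIGAR edit count must equal the
validated `k` and is asserted at emission. Local style keeps the
maximum-scoring contiguous path segment (+1 match / −1 edit) and
soft-clips the rest of the read, excluding clips from `NM`. In a tied
best stratum the primary SAM record is the hit with the lowest chromosome
order, then leftmost coordinate, then forward strand; all further records
carry the secondary flag. Output order is input read order, hits per read
by stratum then coordinate; coordinates are 0-based internally and
1-based only in SAM.

## Synthetic data and evaluation

The generator emulates a resequencing experiment on a uniform i.i.d.
random genome: read origins uniform over positions and strands, per-read
substitution counts uniform on `{0..max_subs}` (substitutions always
change the base, so planted counts are effective edit counts),
optional indels, and FR pairs around a normal fragment length (default
300 ± 30). A repeat-injection helper copies a segment to random loci to
exercise ambiguity handling. What this does *not* model: real genomes'
repeat and GC structure, position-dependent sequencing error profiles,
quality-value correlation, and indel-rich error modes — so passing tests
demonstrate algorithmic correctness under controlled conditions, not
field accuracy on real libraries. Evaluation uses the origin criterion
(same chromosome and strand, start within `tolerance_bp = 5`), a
deliberate simplification of interval-equivalence benchmark machinery:
sensitivity = any correct reported hit, recall = correct primary hit,
precision = correct among unambiguously (exactly once) mapped reads.

## Problem sizes and determinism

Default verification runs use a 1 Mb genome with 1,000 reads of length
100 carrying at most 4 substitutions (error rate below 5%, inside the
pigeonhole guarantee for `q = 16`), where all-mode mapping at threshold
60 attains 100% sensitivity. Property suites run the index oracle on
1,000 randomized texts (`q ∈ 2..8` plus spot checks at 16) and the
distance oracle on 1,000 random read/window pairs. Every source of
randomness (genome, reads, ambiguity replacement) flows from explicit
seeds; for fixed seed, inputs and configuration the SAM body is
byte-identical across reruns — all sorts are stable, and batches are
currently processed serially (the `threads` parameter is accepted for
interface completeness but does not yet shard batches).

## Known limitations

- No BAM/CRAM output, no affine gaps, no base-quality-aware likelihoods
  (the exponential identity-based likelihood deliberately replaces
  miscall-probability products), no split-read calling.
- Indels larger than half the band width cannot be recovered as full
  matches, only as clipped partial alignments.
- Frequent-q-gram masking is per chromosome, mirroring per-chromosome
  streaming; a genome-wide cap may behave differently on fragmented
  assemblies.
- Building at `q = 16` transiently needs ~1.5 GiB for the group and rank
  arrays.
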