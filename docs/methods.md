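# Methods and design notes

This note records what the toolkit implements, the choices made where
the formats or the analysis definitions leave room, and what the test
strategy does and does not establish.

## Scope and model

The package implements the full VCF/BCF stack from the published format
specifications: BGZF compression, tabix (.tbi) interval indexing, the
VCFv4.x text grammar, the BCF2.2 binary encoding, and a streaming
object model (reader, writer, header, record) over all of it.  On top
sit three analyses: per-sample heterozygosity counting, extraction of a
single FORMAT item into a typed samples × variants matrix, and a
per-sample/per-file variant summary.  Out of scope by design: remote
(URL) inputs, the CSI index dialect, multi-file merging, on-the-fly
sorting, indel normalization, and plotting.

## Format-layer choices

**BGZF.** Maximum payload per block is 65 280 bytes — 256 bytes of
headroom under 2¹⁶ so the compressed member always fits the 16-bit
BSIZE field even for incompressible input; if a high compression level
still overflows, the block is re-emitted with stored (level-0) deflate,
which cannot overflow.  Default compression level is 6; level 0 writes
stored blocks.  The reader caches exactly one decompressed block and
the writer buffers at most one block of payload, so both ends run in
constant memory.  Plain (non-blocked) gzip input is accepted for
sequential reading but rejected for random access, which needs block
structure.  The end-of-file marker is the canonical 28-byte empty
block, emitted exactly once at close.

**Tabix.** Only the `.tbi` dialect with the VCF preset (format=2,
sequence column 1, begin column 2, meta `#`) is implemented: a 2²⁹-bp
binnable range, 5 bin levels, 16 384-bp linear-index windows.  Records
whose span crosses 2²⁹ raise an indexing error.  Region strings are
1-based inclusive (the samtools convention); all internal arithmetic is
0-based half-open, converted exactly once at the parse boundary.  A
record's span for overlap purposes is
`[POS-1, POS-1 + max(len(REF), END-POS+1))`, so symbolic structural
variants are matched over their INFO END extent, not just their POS.
Queries merge candidate chunks closer than 2¹⁶ virtual units: one seek
costs more than decompressing an adjacent block, and merging cannot
change results, only the amount read.  The written index includes the
per-contig metadata pseudo-bin (37450) htslib expects, making the files
exchangeable with tabix in both directions.

**Text model.** QUAL `.` is missing, never 0; FILTER `.` means "no
filter applied" and is distinct from PASS (a PASS-only filter rejects
it).  Floats print as the shortest decimal that round-trips, and
integral values print without a decimal point, so parse∘format is the
identity on canonicalized lines.  Validation (undeclared body ids,
Number=A/R/G cardinality against the allele count) is advisory by
default and escalates to an error under the reader's strict flag:
real-world files violate the declaration rule constantly, but the rule
is part of the format, so the strict path must exist.

**BCF.** Version 2.2 sentinels and magic; 2.1 input is read best-effort
with a warning.  Bodies are always BGZF-wrapped on write (the common
on-disk form); raw uncompressed bodies are still sniffed and read.
Written headers carry explicit `IDX=` attributes so any reader
reconstructs identical dictionaries; on input, implicit indices follow
declaration order (PASS pinned to 0) and mixing explicit with implicit
positions is an error.  Integer vectors use the smallest atom width
holding all concrete values, with the most negative values per width
reserved as missing / end-of-vector sentinels; mixed-ploidy genotype
vectors are padded with end-of-vector.  Floats decoded from float32 are
canonicalized to the shortest decimal that survives the float32 round
trip, so `AF=0.1` emerges as `0.1`, not `0.10000000149`.

## Analysis definitions

**Heterozygote.** A genotype counts as heterozygous iff it is diploid,
both alleles are called, and the two allele indices differ.  Two
consequences are deliberate: the multiallelic call `1/2` *is*
heterozygous (the indices differ) — recode genotypes upstream if a
biallelic-only definition is wanted — and any missing allele
disqualifies the call, because a half-called genotype is not a
confident het.  Haploid and polyploid calls never count.

**Default filter.** The default screen keeps SNP records with FILTER
containing PASS and QUAL ≥ 9, each part switchable; a missing QUAL
fails any quality threshold, including 0 (conservative: absence of
evidence is not evidence of quality).

**One FORMAT item per table pass.** `vcftable` reads exactly one FORMAT
item, by contract.  This is what keeps the result a rectangular, typed
matrix (integer read depths stay integers; genotype matrices are int8
allele indices) rather than a ragged text table; asking for two items
raises a dedicated error instead of silently concatenating strings.

**Summary attribution.** Per-sample category counters attribute a
record to a sample only when that sample's genotype carries at least
one called non-reference allele, so hom-ref carriers are not counted as
"having" the variant.  The counter set (SNP/INDEL/SV/MNP/OTHER,
multiallelic, het, hom-alt, missing per sample; record, per-contig and
per-category totals per file) is this package's documented choice, not
a claim of equivalence with any other tool's summary panels.

**Streaming vs two-step.** The reader yields one decoded record at a
time and holds no others (`resident_record` makes this assertable);
`two_step_load` materializes everything first and must produce an
identical table to the streaming `vcftable` — an equivalence the tests
pin under region and sample restriction as well.

## The synthetic generator

The generator emulates the structure of a short-read cohort callset:
coordinate-sorted sites with an exact 60/30/5/5 SNP/INDEL/SV/MNP mix
(assignment by largest-remainder apportionment, then a seeded shuffle —
so the mix is exact at any n, not approximate), 10% multiallelic
SNP/INDEL sites, allele frequencies from Beta(1, 3) (skewed toward rare
alternates, as site-frequency spectra are), 2% missing genotype calls,
half of calls phased, 5% haploid samples (mixed ploidy), QUAL uniform
on [0, 60), and FILTER drawn 80/10/10 from PASS / `.` / `q10`.  FORMAT
carries GT, DP (Poisson, mean 20) and GQ (uniform 0–99).  Positions are
drawn without replacement per contig and sorted, capped below the 2²⁹
index limit with headroom for SV END coordinates.

Everything the analyses later measure is recorded at generation time:
per-sample het counts under all 8 filter combinations, per-sample
carried-category counts, the DP matrix, per-contig totals, position
lists.  A deliberately simple second parser in the test suite recounts
hets from the emitted text to guard against a bug shared between
generator and library.

What the generator does *not* emulate: linkage disequilibrium,
population structure, Hardy–Weinberg genotype proportions (alleles are
drawn independently), error/depth correlations, realistic indel length
spectra.  Passing tests therefore establish format correctness and
exact bookkeeping, not robustness to every artifact of real callsets —
though the adversarial suite (mixed ploidy, all-missing genotypes,
symbolic alleles with END, `1/2` hets, missing QUAL/FILTER, an
undeclared body tag, an empty body) covers the structural corners where
parsers typically break.

## Problem sizes and verification

The acceptance checks run the package at the largest sizes that keep
the full verification cycle comfortable on a single core: a 200-sample
× 10 000-variant cohort for the heterozygosity screen (1 600
sample-level counts recovered exactly under 8 filter settings), a
50 000-variant, 3-contig callset with 500 randomized region queries
against a vectorized linear-scan oracle, 1 000 random payloads through
the BGZF codec, and 10 000 random intervals against a full enumeration
of all 37 449 bin spans.  Independent implementations serve as oracles
where they exist: htslib (via pysam) must accept our BCF
record-for-record and its tabix indices must answer queries identically
to ours; Python's gzip must decompress our BGZF streams.

## Known limitations

* `.tbi` only; files indexed with CSI (required beyond 2²⁹ bp) are not
  supported.
* The reader decodes whole records; there is no lazy partial INFO
  decoding for BCF, so heavily annotated files pay full decode cost.
* Pure-Python throughput is orders of magnitude below htslib; the
  target is correctness, portability and readability, not speed on
  biobank-scale data.
* Standard-input reading buffers the stream in memory (no seeking on
  pipes).
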