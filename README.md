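# vcfbox

A self-contained Python toolkit for the Variant Call Format and its
binary companion: every layer a variant file touches is implemented here
from the format specifications — BGZF block compression with
virtual-offset random access, tabix-style interval indexing, the VCF
text and BCF2 binary codecs, a streaming reader/writer object model, and
the analysis operations a cohort screen needs (per-sample
heterozygosity, single-FORMAT-item matrix extraction, variant
summaries).  It is written for computational geneticists who want to
read, subset, convert and analyze VCF/BCF from Python without a compiled
dependency, and for anyone who wants a readable, tested reference for
how these formats actually work.

Interoperability is part of the contract: emitted `.vcf.gz` files are
standard BGZF (any gzip reader decompresses them), emitted `.bcf` files
are BCF2.2 readable by htslib-based tools, and `.tbi` indices are
exchangeable with tabix in both directions.

## The formats and operations at the core

**BGZF** is gzip restricted to independent members of ≤ 64 KiB.  A
*virtual offset* `coffset << 16 | uoffset` (compressed offset of a
block, offset within its decompressed payload) addresses any byte of
the logical stream, which is what makes random access into compressed
text possible.

**Tabix indexing** assigns each record's reference span
`[POS-1, POS-1 + max(len(REF), END-POS+1))` to the smallest bin of a
5-level hierarchy over a 2²⁹-bp range (bins 0…37448), recording for
each bin the virtual-offset *chunks* holding its records, plus a linear
index of the lowest offset per 16-kb window.  A region query unions the
bins overlapping the query (`reg2bins`), prunes chunks with the linear
index, and decodes only the blocks that can contain hits.

**BCF2** replaces ids with positions in the header's string dictionary
(`PASS` is always index 0) and values with typed binary vectors; a
genotype allele is packed as `(allele + 1) << 1 | phased`, 0 for
missing, so `0|1` becomes `[2, 5]`.

**Per-sample heterozygosity**: sample *s* counts site *v* when *v*
passes the enabled filters (SNP-only, FILTER PASS, QUAL ≥ threshold;
default 9) and *s*'s genotype is diploid, fully called, with two
different allele indices.

## A worked example

```python
from vcfbox import FixtureConfig, HetFilter, convert, count_hets, generate

text, truth = generate(FixtureConfig(seed=7, n_samples=5, n_variants=2000))
open("cohort.vcf", "w").write(text)
convert("cohort.vcf", "cohort.vcf.gz")

counts = count_hets("cohort.vcf.gz",
                    HetFilter(snp_only=True, pass_only=True, min_qual=9))
print(counts)
```

prints

```
S1    228
S2    242
S3    253
S4    253
S5    251
Name: het_count, dtype: int64
```

— for each of the five synthetic samples, the number of called diploid
genotypes with two different allele indices at PASS SNP sites with
QUAL ≥ 9.  These equal the counts the generator planted
(`truth.het_counts[(True, True, 9.0)]`), which is the package's core
correctness property: analyses recover construction exactly.

The `examples/` directory holds one short script per capability
(heterozygosity counting, depth-matrix extraction, indexed region
fetch, format conversion, variant summary), each printing the numbers
it computes and what they mean.  The same operations are available from
the shell:

```sh
vcfbox synth -o cohort.vcf --seed 7 --samples 5 --variants 2000
vcfbox view cohort.vcf -o cohort.vcf.gz
vcfbox index cohort.vcf.gz
vcfbox hets cohort.vcf.gz --region chr21
vcfbox table cohort.vcf.gz -f DP --samples S1,S2 --snp-only --pass-only
vcfbox summary cohort.vcf.gz
```

## Layout

| module | contents |
|---|---|
| `vcfbox.bgzf` | BGZF blocks, virtual offsets, streaming reader/writer |
| `vcfbox.tabix` | binning arithmetic, index build/query, `.tbi` I/O, regions |
| `vcfbox.header` / `vcfbox.record` | header and record object model, validation, classification, genotypes |
| `vcfbox.bcf` | BCF2.2 typed values, dictionary headers, record codec |
| `vcfbox.io` | format sniffing, `VcfReader`/`VcfWriter`, conversion |
| `vcfbox.ops` | `count_hets`, `vcftable`, `two_step_load`, `vcfsummary` |
| `vcfbox.synth` | deterministic fixture generator with planted truth |
| `vcfbox.cli` | `vcfbox` command-line tool |

Design notes and modeling choices are documented in
[docs/methods.md](docs/methods.md).
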