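"""Deterministic synthetic-VCF generator with planted ground truth.

Every quantity the analysis layer later estimates — per-sample
heterozygote counts under each filter combination, per-sample variant
category counts, the read-depth matrix, per-contig record totals — is
recorded exactly at generation time, so tests compare estimates against
construction rather than against another parser.

The generator emulates the structure of a short-read cohort callset:
coordinate-sorted biallelic-dominated sites with a configurable mix of
SNP/INDEL/MNP and symbolic structural variants, Beta-distributed allele
frequencies, a missing-genotype rate, partial phasing, a few haploid
samples (mixed ploidy), uniform site qualities and a FILTER column mixing
``PASS``, ``.`` and a quality filter.  It does not emulate linkage
disequilibrium, error-profile correlations, or population structure.

Identical ``FixtureConfig`` (same seed included) → byte-identical VCF
text: category counts are made exact by assignment (not sampling), and a
single seeded generator drives all draws in a fixed order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import VcfboxError

_SNP_ALTS = {"A": "GCT", "C": "TAG", "G": "ACT", "T": "CAG"}
_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic callset.

    Defaults mirror a small cohort: 200 samples, 10 000 variants on one
    contig, 60/30/5/5 SNP/INDEL/SV/MNP mix, low-frequency-skewed allele
    frequencies (Beta(1,3)), 2% missing calls, half the calls phased,
    5% haploid samples, QUAL uniform on [0, 60), 80% PASS sites.
    """

    seed: int = 0
    n_samples: int = 200
    n_variants: int = 10_000
    contigs: tuple[tuple[str, int], ...] = (("chr21", 46_709_983),)
    category_mix: tuple[tuple[str, float], ...] = (
        ("SNP", 0.60), ("INDEL", 0.30), ("SV", 0.05), ("MNP", 0.05),
    )
    multiallelic_fraction: float = 0.10
    af_beta: tuple[float, float] = (1.0, 3.0)
    missing_rate: float = 0.02
    phased_fraction: float = 0.50
    haploid_sample_fraction: float = 0.05
    qual_range: tuple[float, float] = (0.0, 60.0)
    filter_mix: tuple[tuple[str, float], ...] = (
        ("PASS", 0.80), (".", 0.10), ("q10", 0.10),
    )
    format_items: tuple[str, ...] = ("GT", "DP", "GQ")
    dp_mean: float = 20.0

    def __post_init__(self) -> None:
        for name, mix in (("category_mix", self.category_mix),
                          ("filter_mix", self.filter_mix)):
            total = sum(p for _, p in mix)
            if abs(total - 1.0) > 1e-9:
                raise VcfboxError(f"{name} proportions sum to {total}, not 1")
        if self.n_variants < 0 or self.n_samples < 0:
            raise VcfboxError("n_variants and n_samples must be >= 0")
        if "GT" in self.format_items and self.format_items[0] != "GT":
            raise VcfboxError("GT must come first among FORMAT items")


#: the 8 heterozygosity filter settings the truth tables are keyed by
HET_FILTER_COMBOS = tuple(
    itertools.product((False, True), (False, True), (0.0, 9.0))
)


@dataclass
class TruthTables:
    """Ground truth recorded while the fixture was generated."""

    samples: list[str]
    #: (snp_only, pass_only, min_qual) -> per-sample het counts
    het_counts: dict[tuple[bool, bool, float], np.ndarray]
    #: category -> per-sample counts of carried variants (>=1 non-ref allele)
    category_counts: dict[str, np.ndarray]
    per_sample_het: np.ndarray
    per_sample_hom_alt: np.ndarray
    per_sample_missing: np.ndarray
    per_sample_multiallelic: np.ndarray
    dp_matrix: np.ndarray | None          # samples × variants, -1 = missing
    per_contig_counts: dict[str, int]
    positions: dict[str, list[int]]       # sorted POS per contig
    categories: list[str]                 # per-variant category
    quals: list[float]
    filters: list[str]


def _exact_counts(n: int, mix, rng) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` among categories, shuffled."""
    labels = [k for k, _ in mix]
    props = np.array([p for _, p in mix])
    base = np.floor(props * n).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(props * n - base))
    base[order[:rem]] += 1
    assignment = np.repeat(np.arange(len(labels)), base)
    rng.shuffle(assignment)
    return np.array(labels)[assignment]


def generate(config: FixtureConfig) -> tuple[str, TruthTables]:
    """Emit a coordinate-sorted, validation-clean VCF and its truth tables."""
    rng = np.random.default_rng(config.seed)
    n_v, n_s = config.n_variants, config.n_samples
    samples = [f"S{i + 1}" for i in range(n_s)]
    contigs = dict(config.contigs)

    # apportion variants to contigs proportionally to length, exact
    lengths = np.array([ln for _, ln in config.contigs], dtype=float)
    contig_mix = [(name, ln / lengths.sum()) for (name, _), ln
                  in zip(config.contigs, lengths)]
    contig_of = _exact_counts(n_v, contig_mix, rng)
    per_contig = {name: int((contig_of == name).sum()) for name, _ in config.contigs}
    positions: dict[str, np.ndarray] = {}
    for name, length in config.contigs:
        k = per_contig[name]
        # leave headroom below the 2^29 index limit for SV END coordinates
        room = min(length - 10, (1 << 29) - 20_000)
        if k > room // 2:
            raise VcfboxError(
                f"contig {name} too short for {k} variants at minimum spacing"
            )
        pos = np.sort(rng.choice(room, size=k, replace=False) + 1)
        positions[name] = pos

    categories = _exact_counts(n_v, config.category_mix, rng)
    multi = rng.random(n_v) < config.multiallelic_fraction
    quals = np.round(rng.uniform(*config.qual_range, size=n_v), 1)
    filt = _exact_counts(n_v, config.filter_mix, rng)
    has_gt = "GT" in config.format_items
    has_dp = "DP" in config.format_items
    has_gq = "GQ" in config.format_items

    n_haploid = int(round(config.haploid_sample_fraction * n_s))
    is_haploid = np.zeros(n_s, dtype=bool)
    if n_haploid:
        is_haploid[rng.choice(n_s, size=n_haploid, replace=False)] = True

    header_lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=q10,Description="Quality below 10">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    ]
    for name, length in config.contigs:
        header_lines.append(f"##contig=<ID={name},length={length}>")
    fmt_decl = {
        "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    }
    for item in config.format_items:
        header_lines.append(fmt_decl[item])
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if n_s:
        cols += "\tFORMAT\t" + "\t".join(samples)
    header_lines.append(cols)

    het = {c: np.zeros(n_s, dtype=np.int64) for c in HET_FILTER_COMBOS}
    cat_counts = {c: np.zeros(n_s, dtype=np.int64)
                  for c in ("SNP", "INDEL", "SV", "MNP")}
    ps_het = np.zeros(n_s, dtype=np.int64)
    ps_hom = np.zeros(n_s, dtype=np.int64)
    ps_miss = np.zeros(n_s, dtype=np.int64)
    ps_multi = np.zeros(n_s, dtype=np.int64)
    dp_mat = np.full((n_s, n_v), -1, dtype=np.int64) if has_dp else None

    body: list[str] = []
    fmt_col = ":".join(config.format_items)
    v = 0
    cat_list: list[str] = []
    qual_list: list[float] = []
    filt_list: list[str] = []
    contig_pos_lists: dict[str, list[int]] = {name: [] for name, _ in config.contigs}
    for name, _length in config.contigs:
        cidx = 0
        for pos in positions[name]:
            cat = str(categories[v])
            is_multi = bool(multi[v]) and cat in ("SNP", "INDEL")
            ref, alts, info_parts = _make_alleles(cat, is_multi, int(pos), rng)
            n_alt = len(alts)

            # allele frequencies over REF + ALTs
            af = rng.beta(*config.af_beta, size=n_alt)
            af = np.round(af / max(af.sum() / 0.95, 1.0), 4)  # keep some REF mass
            probs = np.concatenate([[1.0 - af.sum()], af])
            probs = probs / probs.sum()
            info_parts.insert(0, "AF=" + ",".join(_short_float(a) for a in af))

            gt_tokens, flags = _draw_genotypes(
                rng, n_s, probs, is_haploid, config.missing_rate,
                config.phased_fraction,
            ) if has_gt and n_s else (None, None)

            sample_cols = []
            if n_s:
                dp = rng.poisson(config.dp_mean, size=n_s) if has_dp else None
                gq = rng.integers(0, 100, size=n_s) if has_gq else None
                if dp is not None:
                    dp_mat[:, v] = dp
                parts_per_item = []
                for item in config.format_items:
                    if item == "GT":
                        parts_per_item.append(gt_tokens)
                    elif item == "DP":
                        parts_per_item.append([str(x) for x in dp])
                    else:
                        parts_per_item.append([str(x) for x in gq])
                sample_cols = [":".join(p) for p in zip(*parts_per_item)]

            if flags is not None:
                is_het_v, carries, hom_alt, missing = flags
                passes_filter = filt[v] == "PASS"
                for snp_only, pass_only, min_q in HET_FILTER_COMBOS:
                    if snp_only and cat != "SNP":
                        continue
                    if pass_only and not passes_filter:
                        continue
                    if quals[v] < min_q:
                        continue
                    het[(snp_only, pass_only, min_q)] += is_het_v
                cat_counts[cat] += carries
                ps_het += is_het_v
                ps_hom += hom_alt
                ps_miss += missing
                if is_multi:
                    ps_multi += carries

            fields = [
                name, str(int(pos)), ".", ref, ",".join(alts),
                _short_float(quals[v]), str(filt[v]),
                ";".join(info_parts) if info_parts else ".",
            ]
            if n_s:
                fields.append(fmt_col)
                fields.extend(sample_cols)
            body.append("\t".join(fields))
            cat_list.append(cat)
            qual_list.append(float(quals[v]))
            filt_list.append(str(filt[v]))
            contig_pos_lists[name].append(int(pos))
            cidx += 1
            v += 1

    text = "\n".join(header_lines + body) + "\n"
    truth = TruthTables(
        samples=samples,
        het_counts=het,
        category_counts=cat_counts,
        per_sample_het=ps_het,
        per_sample_hom_alt=ps_hom,
        per_sample_missing=ps_miss,
        per_sample_multiallelic=ps_multi,
        dp_matrix=dp_mat,
        per_contig_counts=per_contig,
        positions=contig_pos_lists,
        categories=cat_list,
        quals=qual_list,
        filters=filt_list,
    )
    return text, truth


def _short_float(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(round(float(x), 6)))


def _make_alleles(cat: str, is_multi: bool, pos: int, rng) -> tuple[str, list[str], list[str]]:
    info: list[str] = []
    ref_base = _BASES[rng.integers(4)]
    if cat == "SNP":
        choices = _SNP_ALTS[ref_base]
        if is_multi:
            i = rng.integers(3)
            alts = [choices[i], choices[(i + 1) % 3]]
        else:
            alts = [choices[rng.integers(3)]]
        return ref_base, alts, info
    if cat == "MNP":
        k = int(rng.integers(2, 4))
        ref = "".join(_BASES[rng.integers(4)] for _ in range(k))
        alt = "".join(_SNP_ALTS[c][rng.integers(3)] for c in ref)
        return ref, [alt], info
    if cat == "INDEL":
        ins = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 6))))
        if rng.random() < 0.5:
            ref, alts = ref_base, [ref_base + ins]
        else:
            ref, alts = ref_base + ins, [ref_base]
        if is_multi:
            while True:
                extra = "".join(
                    _BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4)))
                )
                cand = ref[0] + extra
                # a same-length allele would turn the site into a mixed
                # INDEL/MNP class; keep the planted category pure
                if cand != ref and cand not in alts and len(cand) != len(ref):
                    alts.append(cand)
                    break
        return ref, alts, info
    # SV: symbolic allele with explicit END
    svlen = int(rng.integers(100, 10_000))
    svtype = ("DEL", "DUP", "INV")[rng.integers(3)]
    info.append(f"END={pos + svlen}")
    info.append(f"SVTYPE={svtype}")
    return "N", [f"<{svtype}>"], info


def _draw_genotypes(rng, n_s, probs, is_haploid, missing_rate, phased_fraction):
    n_allele = len(probs)
    a1 = rng.choice(n_allele, size=n_s, p=probs)
    a2 = rng.choice(n_allele, size=n_s, p=probs)
    miss = rng.random(n_s) < missing_rate
    phased = rng.random(n_s) < phased_fraction
    tokens: list[str] = []
    is_het_v = np.zeros(n_s, dtype=np.int64)
    carries = np.zeros(n_s, dtype=np.int64)
    hom_alt = np.zeros(n_s, dtype=np.int64)
    missing = np.zeros(n_s, dtype=np.int64)
    for i in range(n_s):
        if miss[i]:
            tokens.append("." if is_haploid[i] else ("./." if not phased[i] else ".|."))
            missing[i] = 1
            continue
        if is_haploid[i]:
            tokens.append(str(a1[i]))
            if a1[i] > 0:
                carries[i] = 1
                hom_alt[i] = 1
            continue
        x, y = int(a1[i]), int(a2[i])
        sep = "|" if phased[i] else "/"
        if phased[i]:
            tokens.append(f"{x}{sep}{y}")
        else:
            lo, hi = min(x, y), max(x, y)
            tokens.append(f"{lo}{sep}{hi}")
        if x != y:
            is_het_v[i] = 1
        elif x > 0:
            hom_alt[i] = 1
        if x > 0 or y > 0:
            carries[i] = 1
    return tokens, (is_het_v, carries, hom_alt, missing)


# --------------------------------------------------------------- edge cases


_ADVERSARIAL_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="Quality below 10">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##contig=<ID=chr21,length=46709983>
##contig=<ID=chr22,length=50818468>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tA3
"""


def adversarial_suite() -> list[tuple[str, str]]:
    """Hand-built edge-case files exercising the corners of the format.

    Mixed ploidy, all-missing genotypes, symbolic alleles with INFO END,
    multiallelic ``1/2`` hets, missing QUAL/FILTER, an undeclared body tag
    (deliberate violation, for strict-mode tests), and an empty body.
    """
    H = _ADVERSARIAL_HEADER
    files = [
        ("mixed_ploidy", H + "\n".join([
            "chr21\t100\t.\tA\tG\t40\tPASS\t.\tGT:DP\t0|1:10\t1:7\t0/1/1:9",
            "chr21\t200\t.\tC\tT\t50\tPASS\t.\tGT:DP\t1|1:12\t0:6\t./.:.",
        ]) + "\n"),
        ("all_missing_gt", H + "\n".join([
            "chr21\t100\t.\tA\tG\t40\tPASS\t.\tGT\t./.\t./.\t.|.",
            "chr21\t200\t.\tC\tT\t.\tPASS\t.\tGT\t.\t./.\t./.",
        ]) + "\n"),
        ("symbolic_sv", H + "\n".join([
            "chr21\t100\t.\tN\t<DEL>\t60\tPASS\tEND=5000;SVTYPE=DEL\tGT\t0/1\t0/0\t1/1",
            "chr21\t9000\t.\tN\t<DUP>\t55\tPASS\tEND=12000;SVTYPE=DUP\tGT\t0/0\t0/1\t./.",
        ]) + "\n"),
        ("multiallelic", H + "\n".join([
            "chr21\t100\trs77\tA\tG,T\t33.3\tPASS\tAF=0.2,0.1\tGT:PL\t1/2:50,20,10,5,0,60\t0/1:0,10,80,12,40,99\t2|2:90,80,70,10,5,0",
            "chr21\t200\t.\tAT\tA,ATT,ACT\t21\tq10\tAF=0.1,0.1,0.05\tGT\t0/3\t1/2\t./.",
        ]) + "\n"),
        ("missing_qual_filter", H + "\n".join([
            "chr21\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/1:.\t0|0:5\t1/1:8",
            "chr22\t50\t.\tC\tT\t0\t.\t.\tGT:DP\t0/1:3\t./.:.\t0/0:2",
        ]) + "\n"),
        ("undeclared_tag", H + "\n".join([
            "chr21\t100\t.\tA\tG\t40\tPASS\t.\tGT:XX\t0/1:7\t0/0:8\t1/1:9",
        ]) + "\n"),
        ("empty_body", H),
    ]
    return files
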