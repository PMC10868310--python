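"""Header and record object model: parsing, mutation, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcfbox.errors import DuplicateIdError, FormatError, VcfboxError
from vcfbox.header import FieldDef, VcfHeader
from vcfbox.record import (
    Genotype,
    VariantType,
    classify_variant,
    format_record,
    is_het,
    parse_genotype,
    parse_record,
    validate_record,
)

HDR = """##fileformat=VCFv4.2
##contig=<ID=chr21,length=46709983>
##FILTER=<ID=q10,Description="Quality below 10">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Genotype likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


@pytest.fixture(scope="module")
def header():
    return VcfHeader.parse(HDR.splitlines())


# ----------------------------------------------------------------- header


def test_header_parse_and_serialize_round_trip(header):
    assert header.samples == ["S1", "S2", "S3"]
    assert header.contigs == {"chr21": 46709983}
    assert header.infos["AF"].number == "A"
    assert header.formats["PL"].number == "G"
    assert header.to_text() == HDR


def test_minimal_header_has_no_samples():
    h = VcfHeader.parse([
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ])
    assert h.samples == []
    assert "PASS" in h.filters  # implicit


def test_missing_fileformat_warns_and_defaults():
    with pytest.warns(UserWarning, match="fileformat"):
        h = VcfHeader.parse(["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"])
    assert h.fileformat == "VCFv4.2"


def test_duplicate_declaration_rejected():
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="a">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="b">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    with pytest.raises(DuplicateIdError):
        VcfHeader.parse(lines)


def test_missing_chrom_line_rejected():
    with pytest.raises(FormatError, match="#CHROM"):
        VcfHeader.parse(["##fileformat=VCFv4.2"])


def test_header_mutation_add_remove_inverse(header):
    h = VcfHeader.parse(HDR.splitlines())
    h.add_field("format", FieldDef("GQ", 1, "Integer", "Genotype quality"))
    assert "##FORMAT=<ID=GQ,Number=1,Type=Integer" in h.to_text()
    h.remove_field("format", "GQ")
    assert h.to_text() == HDR
    with pytest.raises(VcfboxError):
        h.remove_field("filter", "nonexistent")
    with pytest.raises(DuplicateIdError):
        h.add_field("info", FieldDef("DP", 1, "Integer", "dup"))


def test_string_dictionary_pass_is_index_zero(header):
    d = header.string_dictionary()
    assert d[0] == "PASS"
    assert set(d) >= {"PASS", "q10", "DP", "AF", "DB", "GT", "PL"}
    # shared id across INFO and FORMAT occupies one slot
    assert d.count("DP") == 1


def test_flag_with_nonzero_number_rejected():
    with pytest.raises(FormatError):
        FieldDef("X", 1, "Flag", "bad")


# ----------------------------------------------------------------- record


def test_parse_record_basics(header):
    line = "chr21\t5\t.\tA\tG\t30\tPASS\t.\tGT\t0|1\t0/0\t./."
    r = parse_record(line, header)
    assert (r.chrom, r.pos, r.ref, r.alts) == ("chr21", 5, "A", ["G"])
    assert r.qual == 30.0
    assert r.filters == ["PASS"]
    g = r.genotypes()
    assert g[0].alleles == (0, 1) and g[0].phased == (True,)
    assert format_record(r) == line


def test_missing_qual_is_not_zero(header):
    r = parse_record("chr21\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0", header)
    assert r.qual is None
    r0 = parse_record("chr21\t5\t.\tA\tG\t0\tPASS\t.\tGT\t0/0\t0/0\t0/0", header)
    assert r0.qual == 0.0


def test_missing_filter_distinct_from_pass(header):
    r = parse_record("chr21\t5\t.\tA\tG\t9\t.\t.\tGT\t0/0\t0/0\t0/0", header)
    assert r.filters is None


def test_wrong_column_count_rejected(header):
    with pytest.raises(FormatError, match="columns"):
        parse_record("chr21\t5\t.\tA\tG\t30\tPASS\t.\tGT\t0|1", header)
    with pytest.raises(FormatError, match="POS"):
        parse_record("chr21\tXX\t.\tA\tG\t30\tPASS\t.\tGT\t0|1\t0/0\t./.", header)


def test_record_round_trip_on_fixture_lines(small_fixture):
    from vcfbox.io import VcfReader

    with VcfReader(small_fixture["vcf"]) as reader:
        hdr = reader.header
    body = [l for l in small_fixture["text"].splitlines() if not l.startswith("#")]
    for line in body[::7]:
        assert format_record(parse_record(line, hdr)) == line


# --------------------------------------------------------------- genotypes


@pytest.mark.parametrize(
    "token,alleles,phased",
    [
        ("0|1", (0, 1), (True,)),
        ("./.", (None, None), (False,)),
        ("1/2", (1, 2), (False,)),
        ("1", (1,), ()),
        (".", (None,), ()),
        ("0/1/2", (0, 1, 2), (False, False)),
        (".|1", (None, 1), (True,)),
    ],
)
def test_parse_genotype(token, alleles, phased):
    g = parse_genotype(token)
    assert g.alleles == alleles and g.phased == phased
    assert str(g) == token


@pytest.mark.parametrize(
    "alleles,expected",
    [
        ((0, 1), True),
        ((1, 2), True),
        ((1, 1), False),
        ((0, 0), False),
        ((None, 1), False),
        ((1,), False),
        ((0, 1, 2), False),
    ],
)
def test_is_het_definition(alleles, expected):
    phased = tuple(False for _ in alleles[1:])
    assert is_het(Genotype(alleles, phased)) is expected


def test_genotype_matrix_widths_agree(header):
    line = "chr21\t5\t.\tA\tG,T\t30\tPASS\t.\tGT\t0|1\t1/2\t./."
    r = parse_record(line, header)
    small = r.genotype_matrix("small-int")
    full = r.genotype_matrix("full-int")
    pres = r.genotype_matrix("presence")
    assert small.dtype == np.int8 and full.dtype == np.int32
    assert (small.astype(np.int32) == full).all()
    assert pres.tolist() == [True, True, False]


def test_genotype_matrix_errors(header):
    r = parse_record("chr21\t5\t.\tA\tG\t30\tPASS\tDP=1\tDP\t1\t2\t3", header)
    from vcfbox.errors import NoGenotypeError

    with pytest.raises(NoGenotypeError):
        r.genotypes()


# ------------------------------------------------------------ classification


@pytest.mark.parametrize(
    "ref,alt,expected,multi",
    [
        ("A", "G", VariantType.SNP, False),
        ("A", "G,T", VariantType.SNP, True),
        ("A", "AT", VariantType.INDEL, False),
        ("AT", "A", VariantType.INDEL, False),
        ("AT", "GC", VariantType.MNP, False),
        ("N", "<DEL>", VariantType.SV, False),
        ("A", "A[chr2:100[", VariantType.SV, False),
        ("A", "G,AT", VariantType.OTHER, True),
        ("A", ".", VariantType.OTHER, False),
    ],
)
def test_classify_variant(header, ref, alt, expected, multi):
    line = f"chr21\t5\t.\t{ref}\t{alt}\t30\tPASS\t.\tGT\t0/0\t0/0\t0/0"
    kind, is_multi = classify_variant(parse_record(line, header))
    assert kind is expected and is_multi is multi


def test_classification_invariant_under_alt_reorder(header):
    a = parse_record("chr21\t5\t.\tA\tG,T\t1\t.\t.\tGT\t0/0\t0/0\t0/0", header)
    b = parse_record("chr21\t5\t.\tA\tT,G\t1\t.\t.\tGT\t0/0\t0/0\t0/0", header)
    assert classify_variant(a)[0] is classify_variant(b)[0]


# --------------------------------------------------------------- validation


def test_validate_clean_record(header):
    r = parse_record(
        "chr21\t5\t.\tA\tG\t30\tPASS\tDP=10;AF=0.5;DB\tGT:DP\t0|1:3\t0/0:2\t./.:.",
        header,
    )
    assert validate_record(header, r) == []


def test_validate_undeclared_ids(header):
    r = parse_record(
        "chr21\t5\t.\tA\tG\t30\tq99\tXX=1\tGT:ZZ\t0|1:3\t0/0:2\t./.:.", header
    )
    msgs = "\n".join(validate_record(header, r))
    assert "q99" in msgs and "XX" in msgs and "ZZ" in msgs


def test_validate_cardinality_a_against_allele_count(header):
    r = parse_record(
        "chr21\t5\t.\tA\tG\t30\tPASS\tAF=0.5,0.5\tGT\t0|1\t0/0\t./.", header
    )
    msgs = validate_record(header, r)
    assert any("AF" in m and "Number=A" in m for m in msgs)
    # PL: Number=G, diploid biallelic expects 3 values
    ok = parse_record(
        "chr21\t5\t.\tA\tG\t30\tPASS\t.\tGT:PL\t0|1:1,2,3\t0/0:4,5,6\t./.:.",
        header,
    )
    assert validate_record(header, ok) == []
    bad = parse_record(
        "chr21\t5\t.\tA\tG\t30\tPASS\t.\tGT:PL\t0|1:1,2\t0/0:4,5,6\t./.:.",
        header,
    )
    assert any("PL" in m for m in validate_record(header, bad))


# ----------------------------------------------------------- property test


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=3),
            st.integers(min_value=0, max_value=3),
            st.booleans(),
        ),
        min_size=1,
        max_size=6,
    )
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_genotype_token_round_trip(calls):
    for a, b, ph in calls:
        sep = "|" if ph else "/"
        token = f"{a}{sep}{b}"
        g = parse_genotype(token)
        assert str(g) == token
        assert g.ploidy == 2
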