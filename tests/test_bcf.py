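"""BCF2 codec: typed values, GT packing, header/record round trips,
agreement with an independent htslib-based reader."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcfbox import bcf
from vcfbox.bgzf import BgzfWriter
from vcfbox.errors import DictionaryError, FormatError
from vcfbox.header import VcfHeader
from vcfbox.io import VcfReader, convert
from vcfbox.record import format_record, parse_genotype, parse_record

HDR = """##fileformat=VCFv4.2
##contig=<ID=chr21,length=46709983>
##FILTER=<ID=q10,Description="Quality below 10">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


@pytest.fixture(scope="module")
def header():
    return VcfHeader.parse(HDR.splitlines())


# ------------------------------------------------------------ typed values


def test_typed_single_int_example():
    vals, btype, used = bcf.decode_typed(bytes([0x11, 0x05]))
    assert vals == [5] and btype == bcf.BT_INT8 and used == 2


def test_typed_width_selection_minimal():
    out = bytearray()
    bcf.encode_typed(out, [300])
    assert out[0] & 0x0F == bcf.BT_INT16
    out = bytearray()
    bcf.encode_typed(out, [70000])
    assert out[0] & 0x0F == bcf.BT_INT32
    out = bytearray()
    bcf.encode_typed(out, [1, 2, 3])
    assert out[0] & 0x0F == bcf.BT_INT8


def test_typed_reserved_code_rejected():
    with pytest.raises(FormatError):
        bcf.decode_typed(bytes([0x14, 0x00]))  # type code 4 is reserved
    with pytest.raises(FormatError):
        bcf.decode_typed(bytes([0x31, 0x01]))  # truncated int vector


@given(
    st.lists(
        st.one_of(
            st.integers(min_value=-(1 << 30), max_value=(1 << 30)),
            st.none(),
        ),
        min_size=0,
        max_size=10,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_typed_int_round_trip_with_sentinels(values):
    out = bytearray()
    bcf.encode_typed(out, values)
    decoded, _, used = bcf.decode_typed(bytes(out))
    assert used == len(out)
    assert decoded == values


def test_typed_long_vector_count_spills():
    values = list(range(100))
    out = bytearray()
    bcf.encode_typed(out, values)
    assert out[0] >> 4 == 15  # count escapes into a following typed int
    decoded, _, _ = bcf.decode_typed(bytes(out))
    assert decoded == values


def test_typed_char_round_trip():
    out = bytearray()
    bcf.encode_typed(out, "ACGT,<DEL>")
    decoded, btype, _ = bcf.decode_typed(bytes(out))
    assert decoded == "ACGT,<DEL>" and btype == bcf.BT_CHAR


# ------------------------------------------------------------- GT packing


@pytest.mark.parametrize(
    "token,packed",
    [
        ("0|1", [2, 5]),
        ("./.", [0, 0]),
        ("1", [4]),
        ("1/2", [4, 6]),
        ("0/0", [2, 2]),
        (".|.", [0, 1]),
    ],
)
def test_gt_packing_formula(token, packed):
    assert bcf._pack_gt(parse_genotype(token)) == packed
    assert str(bcf._unpack_gt(packed)) == token


def test_gt_mixed_ploidy_pads_with_end_of_vector():
    g = bcf._unpack_gt([4, bcf.EOV])
    assert g.alleles == (1,) and g.ploidy == 1


# ------------------------------------------------------------ header codec


def test_bcf_header_round_trip(header):
    buf = io.BytesIO()
    bcf.write_bcf_header(buf, header)
    buf.seek(0)
    h2 = bcf.read_bcf_header(buf)
    assert h2 == header
    assert h2.string_dictionary() == header.string_dictionary()
    assert h2.contig_dictionary() == header.contig_dictionary()


def test_bcf_bad_magic_rejected():
    with pytest.raises(FormatError, match="BAM"):
        bcf.read_bcf_header(io.BytesIO(b"BAM\x01\x00\x00\x00\x00\x00"))


def test_bcf_21_version_warns(header):
    buf = io.BytesIO()
    bcf.write_bcf_header(buf, header)
    data = bytearray(buf.getvalue())
    data[4] = 1  # pretend BCF2.1
    with pytest.warns(UserWarning, match="2.1"):
        bcf.read_bcf_header(io.BytesIO(bytes(data)))


def test_explicit_idx_out_of_order_honored():
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="ok",IDX=0>',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="d",IDX=3>',
        '##FILTER=<ID=q10,Description="q",IDX=1>',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g",IDX=2>',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    h = VcfHeader.parse(lines)
    assert h.string_dictionary() == ["PASS", "q10", "GT", "DP"]


# ------------------------------------------------------------ record codec


CASES = [
    "chr21\t5\trs1\tA\tG\t30\tPASS\tDP=10;AF=0.1;DB\tGT:DP\t0|1:12\t1/1:9\t./.:.",
    "chr21\t100\t.\tN\t<DEL>\t.\t.\tEND=500\tGT\t0/1\t0/0\t1",
    "chr21\t200\t.\tAT\tA,ATT\t7.5\tq10\tAF=0.1,0.25\tGT:PL\t1/2:1,2,3,4,5,6\t0/0:.\t.:.",
    "chr21\t300\t.\tC\tT\t0\t.\t.\tGT\t.|.\t0/1/1\t1",
]


@pytest.mark.parametrize("line", CASES)
def test_record_codec_round_trip(header, line):
    rec = parse_record(line, header)
    blob = bcf.encode_record(rec, header)
    rec2, used = bcf.decode_record(blob, header)
    assert used == len(blob)
    assert format_record(rec2) == line


def test_encode_undeclared_id_raises(header):
    rec = parse_record(CASES[0], header)
    rec.info = {"UNDECLARED": 1}
    with pytest.raises(DictionaryError):
        bcf.encode_record(rec, header)


def test_reencoding_never_grows_width(header):
    for line in CASES:
        rec = parse_record(line, header)
        blob = bcf.encode_record(rec, header)
        rec2, _ = bcf.decode_record(blob, header)
        blob2 = bcf.encode_record(rec2, header)
        assert len(blob2) <= len(blob)


def test_float_info_canonical_through_float32(header):
    rec = parse_record(
        "chr21\t5\t.\tA\tG\t31.7\tPASS\tAF=0.1\tGT\t0/0\t0/0\t0/0", header
    )
    rec2, _ = bcf.decode_record(bcf.encode_record(rec, header), header)
    assert rec2.info["AF"] == (0.1,)
    assert rec2.qual == 31.7


# ----------------------------------------------------- external oracle


def test_external_reader_accepts_our_bcf(small_fixture, tmp_path):
    """htslib (via pysam) parses every record of a file we encoded."""
    pysam = pytest.importorskip("pysam")
    out = tmp_path / "ours.bcf"
    convert(small_fixture["vcf"], str(out))
    with VcfReader(small_fixture["vcf"]) as r:
        ours = [x.to_line() for x in r]
    theirs = [str(rec).rstrip("\n") for rec in pysam.VariantFile(str(out))]
    assert theirs == ours


def test_second_external_reader_agrees(small_fixture, tmp_path):
    """cyvcf2 (independent htslib binding) parses our BCF identically."""
    cyvcf2 = pytest.importorskip("cyvcf2")
    out = tmp_path / "ours2.bcf"
    convert(small_fixture["vcf"], str(out))
    theirs = [str(v).rstrip("\n") for v in cyvcf2.VCF(str(out))]
    with VcfReader(small_fixture["vcf"]) as r:
        ours = [x.to_line() for x in r]
    assert theirs == ours


def test_we_read_bcftools_encoded_bcf(small_fixture, tmp_path):
    """A BCF written by an independent implementation decodes identically."""
    pysam = pytest.importorskip("pysam")
    theirs_path = tmp_path / "theirs.bcf"
    with pysam.VariantFile(small_fixture["vcf"]) as src:
        with pysam.VariantFile(str(theirs_path), "wb", header=src.header) as dst:
            for rec in src:
                dst.write(rec)
    with VcfReader(str(theirs_path)) as r:
        ours = [(x.chrom, x.pos, x.ref, tuple(x.alts), x.qual) for x in r]
    with VcfReader(small_fixture["vcf"]) as r:
        base = [(x.chrom, x.pos, x.ref, tuple(x.alts), x.qual) for x in r]
    assert ours == base


def test_vcf_bcf_vcf_equals_text_canonicalization(small_fixture, tmp_path):
    """The module's central property: the binary detour is semantically lossless."""
    bcf_path = tmp_path / "d.bcf"
    back = tmp_path / "back.vcf"
    convert(small_fixture["vcf"], str(bcf_path))
    convert(str(bcf_path), str(back), mode="vcf-plain")
    with VcfReader(small_fixture["vcf"]) as r:
        a = [x.to_line() for x in r]
    with VcfReader(str(back)) as r:
        b = [x.to_line() for x in r]
    assert a == b
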