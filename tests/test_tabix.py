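"""Binning arithmetic, region parsing, index build/query, .tbi round trips."""

import numpy as np
import pytest

from vcfbox import tabix
from vcfbox.bgzf import BgzfReader
from vcfbox.errors import FormatError, RegionParseError, SortOrderError
from vcfbox.io import VcfReader, convert


def _bin_spans():
    """(start, end) span of every bin 0..37448, via the 5-level layout."""
    starts, ends = [], []
    for level in range(6):
        offset = ((1 << (3 * level)) - 1) // 7
        size = 1 << (29 - 3 * level)
        for i in range(1 << (3 * level)):
            starts.append(i * size)
            ends.append((i + 1) * size)
    return np.array(starts), np.array(ends)


_STARTS, _ENDS = _bin_spans()
_SIZES = _ENDS - _STARTS


def brute_reg2bin(beg: int, end: int) -> int:
    contains = (_STARTS <= beg) & (end <= _ENDS)
    candidates = np.flatnonzero(contains)
    return int(candidates[np.argmin(_SIZES[candidates])])


def brute_reg2bins(beg: int, end: int) -> list[int]:
    return np.flatnonzero((_STARTS < end) & (_ENDS > beg)).tolist()


def test_reg2bin_examples():
    assert tabix.reg2bin(0, 1 << 29) == 0
    assert tabix.reg2bin(0, 1) == 4681
    assert tabix.reg2bin(16384, 16385) == 4682


def test_reg2bins_examples():
    assert tabix.reg2bins(0, 1) == [0, 1, 9, 73, 585, 4681]
    assert len(tabix.reg2bins(0, 1 << 29)) == 37449


def test_binning_agrees_with_enumeration_sample():
    rng = np.random.default_rng(42)
    for _ in range(500):
        beg = int(rng.integers(0, 1 << 29))
        end = int(rng.integers(beg + 1, min(beg + 10**7, 1 << 29) + 1))
        assert tabix.reg2bin(beg, end) == brute_reg2bin(beg, end)
        bins = tabix.reg2bins(beg, end)
        assert bins == brute_reg2bins(beg, end)
        assert tabix.reg2bin(beg, end) in bins


def test_binning_range_errors():
    with pytest.raises(ValueError):
        tabix.reg2bin(-1, 5)
    with pytest.raises(ValueError):
        tabix.reg2bins(0, (1 << 29) + 1)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("chr21", ("chr21", 1, None)),
        ("chr21:5000", ("chr21", 5000, None)),
        ("chr21:5,000-10,000", ("chr21", 5000, 10000)),
        ("chr21:1-1", ("chr21", 1, 1)),
    ],
)
def test_region_parsing(text, expected):
    r = tabix.Region.parse(text)
    assert (r.contig, r.start, r.end) == expected


def test_region_parse_errors():
    with pytest.raises(RegionParseError):
        tabix.Region.parse("chr21:10-5")
    with pytest.raises(RegionParseError):
        tabix.Region.parse("")


def test_line_span_honors_info_end():
    assert tabix.line_span("chr1\t100\t.\tA\tG\t.\t.\t.") == ("chr1", 99, 100)
    assert tabix.line_span("chr1\t100\t.\tAT\tA\t.\t.\tDP=3") == ("chr1", 99, 101)
    sv = "chr1\t100\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=500"
    assert tabix.line_span(sv) == ("chr1", 99, 500)


def _index_of(path):
    with open(path, "rb") as fh:
        return tabix.build_index(BgzfReader(fh))


def test_build_index_and_self_query(small_fixture):
    idx = _index_of(small_fixture["gz"])
    assert idx.contig_names == ["chr21", "chr22"]
    truth = small_fixture["truth"]
    for contig, positions in truth.positions.items():
        assert idx.contigs[contig].n_records == len(positions)
    # every planted position self-queries successfully
    with open(small_fixture["gz"], "rb") as fh:
        bg = BgzfReader(fh)
        for contig, positions in truth.positions.items():
            for pos in positions[::17]:  # stride keeps the test quick
                reg = tabix.Region(contig, pos, pos)
                lines = list(tabix.fetch_lines(bg, idx, reg))
                assert any(int(l.split("\t")[1]) == pos for l in lines)


def test_query_matches_linear_scan(small_fixture):
    idx = _index_of(small_fixture["gz"])
    with VcfReader(small_fixture["gz"]) as r:
        recs = [(x.chrom, x.pos - 1, x.end, x.to_line()) for x in r]
    rng = np.random.default_rng(7)
    contigs = ["chr21", "chr22", "chrMissing"]
    for _ in range(60):
        c = contigs[rng.integers(3)]
        beg = int(rng.integers(1, 46_000_000))
        end = beg + int(rng.integers(1, 8_000_000))
        reg = tabix.Region(c, beg, end)
        expected = [l for ch, b0, e0, l in recs
                    if ch == c and b0 < reg.end0 and e0 > reg.beg0]
        with open(small_fixture["gz"], "rb") as fh:
            got = list(tabix.fetch_lines(BgzfReader(fh), idx, reg))
        assert got == expected


def test_query_absent_contig_is_empty(small_fixture):
    idx = _index_of(small_fixture["gz"])
    assert idx.query(tabix.Region("chrNope", 1, 100)) == []


def test_whole_contig_region_returns_all_records(small_fixture):
    idx = _index_of(small_fixture["gz"])
    truth = small_fixture["truth"]
    with open(small_fixture["gz"], "rb") as fh:
        got = list(tabix.fetch_lines(BgzfReader(fh), idx, tabix.Region("chr22")))
    assert len(got) == truth.per_contig_counts["chr22"]


def test_tbi_round_trip(small_fixture, tmp_path):
    idx = _index_of(small_fixture["gz"])
    p = tmp_path / "rt.tbi"
    tabix.write_tbi(idx, str(p))
    idx2 = tabix.read_tbi(str(p))
    assert idx2.contig_names == idx.contig_names
    for c in idx.contig_names:
        assert idx2.contigs[c].bins == idx.contigs[c].bins
        assert idx2.contigs[c].linear == idx.contigs[c].linear
    assert idx2.meta == idx.meta


def test_tbi_bad_magic_and_truncation(tmp_path, small_fixture):
    import vcfbox.bgzf as bgzf

    bad = tmp_path / "bad.tbi"
    bad.write_bytes(bgzf.compress_block(b"NOPE" + b"\x00" * 40) + bgzf.BGZF_EOF)
    with pytest.raises(FormatError):
        tabix.read_tbi(str(bad))
    trunc = tmp_path / "trunc.tbi"
    trunc.write_bytes(bgzf.compress_block(b"TBI\x01\x02\x00") + bgzf.BGZF_EOF)
    with pytest.raises(FormatError):
        tabix.read_tbi(str(trunc))


def test_htslib_index_interoperability(small_fixture, tmp_path):
    """An htslib-produced .tbi on the same file yields identical queries."""
    pysam = pytest.importorskip("pysam")
    import shutil

    gz = tmp_path / "ht.vcf.gz"
    shutil.copy(small_fixture["gz"], gz)
    pysam.tabix_index(str(gz), preset="vcf", force=True)
    ours = _index_of(small_fixture["gz"])
    theirs = tabix.read_tbi(str(gz) + ".tbi")
    rng = np.random.default_rng(3)
    for _ in range(40):
        c = ["chr21", "chr22"][rng.integers(2)]
        beg = int(rng.integers(1, 46_000_000))
        reg = tabix.Region(c, beg, beg + int(rng.integers(1, 5_000_000)))
        with open(small_fixture["gz"], "rb") as fh:
            a = list(tabix.fetch_lines(BgzfReader(fh), ours, reg))
        with open(small_fixture["gz"], "rb") as fh:
            b = list(tabix.fetch_lines(BgzfReader(fh), theirs, reg))
        assert a == b


def test_unsorted_input_raises_naming_offender(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t500\t.\tA\tG\t30\tPASS\t.\n"
        "chr1\t100\t.\tC\tT\t30\tPASS\t.\n"
    )
    vcf = tmp_path / "unsorted.vcf"
    vcf.write_text(text)
    gz = tmp_path / "unsorted.vcf.gz"
    convert(str(vcf), str(gz))
    with open(gz, "rb") as fh:
        with pytest.raises(SortOrderError, match="chr1:100"):
            tabix.build_index(BgzfReader(fh))


def test_reappearing_contig_raises(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        "##contig=<ID=chr2,length=1000000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t100\t.\tA\tG\t30\tPASS\t.\n"
        "chr2\t100\t.\tC\tT\t30\tPASS\t.\n"
        "chr1\t200\t.\tC\tT\t30\tPASS\t.\n"
    )
    vcf = tmp_path / "regroup.vcf"
    vcf.write_text(text)
    gz = tmp_path / "regroup.vcf.gz"
    convert(str(vcf), str(gz))
    with open(gz, "rb") as fh:
        with pytest.raises(SortOrderError, match="chr1"):
            tabix.build_index(BgzfReader(fh))


def test_empty_body_indexes_to_zero_contigs(adversarial_files, tmp_path):
    gz = tmp_path / "empty.vcf.gz"
    convert(adversarial_files["empty_body"], str(gz))
    with open(gz, "rb") as fh:
        idx = tabix.build_index(BgzfReader(fh))
    assert idx.contig_names == []
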