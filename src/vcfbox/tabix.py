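"""Tabix-style interval index over BGZF-compressed, coordinate-sorted VCF.

The index maps genomic intervals to *chunks* — virtual-offset ranges of
the compressed file — via the classical 5-level hierarchical binning of a
2**29-bp coordinate range (bins 0..37448), plus a linear index of the
lowest virtual offset per 16384-bp window that prunes chunks ending
before a query could possibly start.  The on-disk ``.tbi`` format written
here is bit-compatible with the tabix VCF preset, so indices are
exchangeable with htslib in both directions.

Coordinates: region strings are 1-based inclusive (the samtools
convention); everything internal is 0-based half-open.  The conversion
happens exactly once, in :meth:`Region.parse`.
"""

from __future__ import annotations

import io
import re
import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator

from .bgzf import BgzfReader, BgzfWriter, VirtualOffset
from .errors import FormatError, RegionParseError, SortOrderError

MAX_COORD = 1 << 29          # upper bound of the binnable range
LINEAR_SHIFT = 14            # 16384-bp linear-index windows
MAX_BIN = 37448              # last real bin of the 5-level scheme
_PSEUDO_BIN = MAX_BIN + 2    # htslib's per-contig metadata pseudo-bin
#: Chunks whose virtual-offset gap is below this are coalesced; one seek
#: costs more than decompressing a block, and merging never changes results.
CHUNK_MERGE_GAP = 1 << 16

_TBI_MAGIC = b"TBI\x01"

#: tabix VCF preset meta numbers.
VCF_PRESET = dict(format=2, col_seq=1, col_beg=2, col_end=0, meta=ord("#"), skip=0)


def reg2bin(beg: int, end: int) -> int:
    """Smallest bin fully containing the 0-based half-open interval."""
    if not (0 <= beg < end <= MAX_COORD):
        raise ValueError(f"interval [{beg}, {end}) outside [0, 2^29)")
    end -= 1
    if beg >> 14 == end >> 14:
        return ((1 << 15) - 1) // 7 + (beg >> 14)
    if beg >> 17 == end >> 17:
        return ((1 << 12) - 1) // 7 + (beg >> 17)
    if beg >> 20 == end >> 20:
        return ((1 << 9) - 1) // 7 + (beg >> 20)
    if beg >> 23 == end >> 23:
        return ((1 << 6) - 1) // 7 + (beg >> 23)
    if beg >> 26 == end >> 26:
        return ((1 << 3) - 1) // 7 + (beg >> 26)
    return 0


def reg2bins(beg: int, end: int) -> list[int]:
    """All bins whose span overlaps [beg, end), ascending."""
    if not (0 <= beg < end <= MAX_COORD):
        raise ValueError(f"interval [{beg}, {end}) outside [0, 2^29)")
    end -= 1
    bins = [0]
    for shift, offset in ((26, 1), (23, 9), (20, 73), (17, 585), (14, 4681)):
        bins.extend(range(offset + (beg >> shift), offset + (end >> shift) + 1))
    return bins


@dataclass(frozen=True)
class Chunk:
    """Half-open virtual-offset range of the compressed file."""

    begin: int  # packed VirtualOffset
    end: int

    def __post_init__(self) -> None:
        if not self.begin < self.end:
            raise ValueError(f"empty chunk [{self.begin}, {self.end})")


_REGION_RE = re.compile(r"^(?P<chrom>.+?)(?::(?P<beg>[\d,]+)(?:-(?P<end>[\d,]+))?)?$")


@dataclass(frozen=True)
class Region:
    """A query region, 1-based inclusive; ``end=None`` means contig end."""

    contig: str
    start: int = 1
    end: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or (self.end is not None and self.end < self.start):
            raise RegionParseError(
                f"invalid region bounds {self.start}-{self.end} on {self.contig}"
            )

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chr``, ``chr:beg`` or ``chr:beg-end`` (commas allowed)."""
        m = _REGION_RE.match(text.strip())
        if not m or not m.group("chrom"):
            raise RegionParseError(f"cannot parse region string {text!r}")
        beg = m.group("beg")
        end = m.group("end")
        try:
            return cls(
                m.group("chrom"),
                int(beg.replace(",", "")) if beg else 1,
                int(end.replace(",", "")) if end else None,
            )
        except ValueError as exc:
            raise RegionParseError(f"cannot parse region string {text!r}") from exc

    @property
    def beg0(self) -> int:
        """0-based inclusive start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end (contig end mapped to the dialect maximum)."""
        return MAX_COORD if self.end is None else self.end

    def overlaps(self, beg0: int, end0: int) -> bool:
        return beg0 < self.end0 and end0 > self.beg0


@dataclass
class _ContigIndex:
    bins: dict[int, list[Chunk]] = field(default_factory=dict)
    linear: list[int] = field(default_factory=list)
    n_records: int = 0


@dataclass
class TabixIndex:
    """Per-contig bin→chunk mapping plus 16-kb linear index."""

    contig_names: list[str] = field(default_factory=list)
    contigs: dict[str, _ContigIndex] = field(default_factory=dict)
    meta: dict = field(default_factory=lambda: dict(VCF_PRESET))
    n_no_coor: int = 0

    def query(self, region: Region) -> list[Chunk]:
        """Candidate chunks for a region, linear-filtered, sorted, merged.

        An absent contig yields an empty list, not an error.
        """
        cidx = self.contigs.get(region.contig)
        if cidx is None:
            return []
        beg0 = region.beg0
        end0 = min(region.end0, MAX_COORD)
        if beg0 >= end0:
            return []
        window = beg0 >> LINEAR_SHIFT
        min_ioff = cidx.linear[window] if window < len(cidx.linear) else (
            cidx.linear[-1] if cidx.linear else 0
        )
        chunks = []
        for b in reg2bins(beg0, end0):
            for ch in cidx.bins.get(b, ()):
                if ch.end > min_ioff:
                    chunks.append(Chunk(max(ch.begin, min_ioff), ch.end))
        chunks.sort(key=lambda c: (c.begin, c.end))
        merged: list[Chunk] = []
        for ch in chunks:
            if merged and ch.begin <= merged[-1].end + CHUNK_MERGE_GAP:
                if ch.end > merged[-1].end:
                    merged[-1] = Chunk(merged[-1].begin, ch.end)
            else:
                merged.append(ch)
        return merged


_INFO_END_RE = re.compile(r"(?:^|;)END=(\d+)(?:;|$)")


def line_span(line: str) -> tuple[str, int, int]:
    """(contig, beg0, end0) reference span of a VCF body line.

    The span is ``[pos0, pos0 + max(len(REF), END - pos + 1))`` so symbolic
    structural-variant alleles honor their INFO END coordinate.
    """
    fields = line.split("\t", 8)
    if len(fields) < 8:
        raise FormatError(f"VCF body line has {len(fields)} fields, expected >= 8")
    chrom, pos_s, ref, info = fields[0], fields[1], fields[3], fields[7]
    try:
        pos0 = int(pos_s) - 1
    except ValueError as exc:
        raise FormatError(f"non-numeric POS {pos_s!r}") from exc
    span = len(ref)
    m = _INFO_END_RE.search(info)
    if m:
        span = max(span, int(m.group(1)) - pos0)
    return chrom, pos0, pos0 + max(span, 1)


def build_index(bgzf: BgzfReader, meta_char: str = "#") -> TabixIndex:
    """Index a coordinate-sorted BGZF VCF stream opened at its start.

    Raises :class:`SortOrderError` naming the offending record when
    positions decrease within a contig or a contig block reappears.
    """
    index = TabixIndex()
    finished: set[str] = set()
    current: str | None = None
    cidx: _ContigIndex | None = None
    last_beg = -1
    # per-bin open chunk accumulation: bin -> [begin, end]
    open_chunks: dict[int, list[int]] = {}

    def _flush_contig() -> None:
        if cidx is None:
            return
        for b, (cb, ce) in sorted(open_chunks.items()):
            cidx.bins.setdefault(b, []).append(Chunk(cb, ce))
        open_chunks.clear()

    while True:
        voff = bgzf.tell().packed
        line = bgzf.readline()
        if not line:
            break
        text = line.decode("utf-8", "replace").rstrip("\n")
        if not text or text.startswith(meta_char):
            continue
        chrom, beg0, end0 = line_span(text)
        if end0 > MAX_COORD or beg0 < 0:
            raise FormatError(
                f"record at {chrom}:{beg0 + 1} exceeds the 2^29-1 tabix coordinate limit"
            )
        voff_end = bgzf.tell().packed
        if chrom != current:
            if chrom in finished:
                raise SortOrderError(
                    f"contig {chrom} reappears at {chrom}:{beg0 + 1}; "
                    "input must be grouped by contig"
                )
            _flush_contig()
            if current is not None:
                finished.add(current)
            current = chrom
            cidx = _ContigIndex()
            index.contig_names.append(chrom)
            index.contigs[chrom] = cidx
            last_beg = -1
        assert cidx is not None
        if beg0 < last_beg:
            raise SortOrderError(
                f"record {chrom}:{beg0 + 1} is out of order (previous start "
                f"{last_beg + 1})"
            )
        last_beg = beg0
        b = reg2bin(beg0, end0)
        acc = open_chunks.get(b)
        if acc is not None and voff <= acc[1]:
            acc[1] = max(acc[1], voff_end)
        else:
            if acc is not None:
                cidx.bins.setdefault(b, []).append(Chunk(acc[0], acc[1]))
            open_chunks[b] = [voff, voff_end]
        w_beg, w_end = beg0 >> LINEAR_SHIFT, (end0 - 1) >> LINEAR_SHIFT
        if len(cidx.linear) <= w_end:
            cidx.linear.extend([0] * (w_end + 1 - len(cidx.linear)))
        for w in range(w_beg, w_end + 1):
            if cidx.linear[w] == 0 or voff < cidx.linear[w]:
                cidx.linear[w] = voff
        cidx.n_records += 1
    _flush_contig()
    for cidx in index.contigs.values():
        # back-fill empty linear windows with the following window's offset,
        # as htslib does, so lookups never see the 0 placeholder
        prev = 0
        for i, v in enumerate(cidx.linear):
            if v == 0:
                cidx.linear[i] = prev
            else:
                prev = v
    return index


def fetch_lines(bgzf: BgzfReader, index: TabixIndex, region: Region) -> Iterator[str]:
    """Yield exactly the body lines whose span overlaps ``region``, in file order."""
    for chunk in index.query(region):
        bgzf.seek(VirtualOffset.from_packed(chunk.begin))
        while bgzf.tell().packed < chunk.end:
            line = bgzf.readline()
            if not line:
                break
            text = line.decode("utf-8", "replace").rstrip("\n")
            if not text or text.startswith("#"):
                continue
            chrom, beg0, end0 = line_span(text)
            if chrom != region.contig or beg0 >= region.end0:
                return
            if region.overlaps(beg0, end0):
                yield text


def write_tbi(index: TabixIndex, path: str) -> None:
    """Serialize to a ``.tbi`` file (BGZF-wrapped, tabix-compatible)."""
    payload = io.BytesIO()
    m = index.meta
    names = b"".join(n.encode() + b"\x00" for n in index.contig_names)
    payload.write(_TBI_MAGIC)
    payload.write(
        struct.pack(
            "<8i",
            len(index.contig_names),
            m["format"], m["col_seq"], m["col_beg"], m["col_end"],
            m["meta"], m["skip"], len(names),
        )
    )
    payload.write(names)
    for name in index.contig_names:
        cidx = index.contigs[name]
        bins = sorted(cidx.bins.items())
        payload.write(struct.pack("<i", len(bins) + 1))  # +1 pseudo-bin
        for b, chunks in bins:
            payload.write(struct.pack("<Ii", b, len(chunks)))
            for ch in chunks:
                payload.write(struct.pack("<QQ", ch.begin, ch.end))
        # htslib metadata pseudo-bin: file extent + mapped/unmapped counts
        all_chunks = [ch for _, chunks in bins for ch in chunks]
        off_beg = min((ch.begin for ch in all_chunks), default=0)
        off_end = max((ch.end for ch in all_chunks), default=0)
        payload.write(struct.pack("<Ii", _PSEUDO_BIN, 2))
        payload.write(struct.pack("<QQQQ", off_beg, off_end, cidx.n_records, 0))
        payload.write(struct.pack("<i", len(cidx.linear)))
        for v in cidx.linear:
            payload.write(struct.pack("<Q", v))
    payload.write(struct.pack("<Q", index.n_no_coor))
    with open(path, "wb") as fh:
        with BgzfWriter(fh) as w:
            w.write(payload.getvalue())


def read_tbi(path: str) -> TabixIndex:
    """Load a ``.tbi`` index (ours or one written by tabix/htslib)."""
    with open(path, "rb") as fh:
        data = BgzfReader(fh).read()
    if data[:4] != _TBI_MAGIC:
        raise FormatError(
            f"not a tabix index: magic {data[:4]!r} instead of {_TBI_MAGIC!r}"
        )
    off = 4

    def take(fmt: str):
        nonlocal off
        s = struct.Struct(fmt)
        if off + s.size > len(data):
            raise FormatError("truncated tabix index")
        vals = s.unpack_from(data, off)
        off += s.size
        return vals

    n_ref, fmt, col_seq, col_beg, col_end, meta, skip, l_nm = take("<8i")
    names_blob = data[off : off + l_nm]
    off += l_nm
    names = [n.decode() for n in names_blob.split(b"\x00") if n]
    if len(names) != n_ref:
        raise FormatError("tabix index name count mismatch")
    index = TabixIndex(
        meta=dict(
            format=fmt, col_seq=col_seq, col_beg=col_beg,
            col_end=col_end, meta=meta, skip=skip,
        )
    )
    for name in names:
        cidx = _ContigIndex()
        (n_bin,) = take("<i")
        for _ in range(n_bin):
            b, n_chunk = take("<Ii")
            chunks = []
            for _ in range(n_chunk):
                cb, ce = take("<QQ")
                chunks.append((cb, ce))
            if b == _PSEUDO_BIN:
                if chunks:
                    cidx.n_records = chunks[-1][0] if n_chunk == 2 else 0
                continue
            cidx.bins[b] = [Chunk(cb, ce) for cb, ce in chunks if cb < ce]
        (n_intv,) = take("<i")
        cidx.linear = [take("<Q")[0] for _ in range(n_intv)]
        index.contig_names.append(name)
        index.contigs[name] = cidx
    if off + 8 <= len(data):
        index.n_no_coor = struct.unpack_from("<Q", data, off)[0]
    return index
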