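"""BCF2 binary codec: typed values, dictionary-indexed headers, records.

BCF stores the same information as VCF text but replaces every INFO,
FORMAT, FILTER id and contig name with its integer position in the header
dictionary, and every value with a *typed* binary vector: a descriptor
byte ``count<<4 | type-code`` (counts >= 15 spill into a following typed
integer) followed by packed atoms.  Integer atoms reserve their most
negative values as sentinels — one for "missing", one for "end of
vector" (used to pad ragged per-sample vectors, e.g. mixed ploidy).

Genotypes pack each allele as ``(allele + 1) << 1 | phased`` with 0 for a
missing allele, so ``0|1`` becomes ``[2, 5]`` and ``./.`` becomes
``[0, 0]``.

On disk a BCF body is BGZF-wrapped (magic ``BCF\\2\\2`` inside the
compressed stream); version 2.1 input is read best-effort with a warning.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DictionaryError, FormatError
from .header import VcfHeader
from .record import Genotype, VcfRecord

# type codes
BT_NULL, BT_INT8, BT_INT16, BT_INT32, BT_FLOAT, BT_CHAR = 0, 1, 2, 3, 5, 7

INT_MISSING = {BT_INT8: -128, BT_INT16: -(1 << 15), BT_INT32: -(1 << 31)}
INT_EOV = {BT_INT8: -127, BT_INT16: -(1 << 15) + 1, BT_INT32: -(1 << 31) + 1}
_INT_RANGE = {
    BT_INT8: (-120, 127),   # leave sentinel space below
    BT_INT16: (-(1 << 15) + 8, (1 << 15) - 1),
    BT_INT32: (-(1 << 31) + 8, (1 << 31) - 1),
}
_INT_FMT = {BT_INT8: "<b", BT_INT16: "<h", BT_INT32: "<i"}

FLOAT_MISSING_BITS = 0x7F800001
FLOAT_EOV_BITS = 0x7F800002

MISSING = object()  # sentinel distinct from None? no — None is missing
EOV = "__EOV__"     # end-of-vector padding marker in decoded value tuples

MAGIC = b"BCF\x02\x02"


def _float_bits(x: float) -> int:
    return struct.unpack("<I", struct.pack("<f", x))[0]


def _bits_float(b: int) -> float:
    return struct.unpack("<f", struct.pack("<I", b))[0]


def canonical_float(x: float) -> float:
    """Shortest decimal value that survives a float32 round trip.

    Decoding ``0.1`` stored as float32 must print ``0.1`` again, not
    ``0.10000000149``; numpy's unique shortest-repr does exactly this.
    """
    return float(np.format_float_positional(np.float32(x), unique=True))


# --------------------------------------------------------------- typed I/O


def _enc_size(out: bytearray, count: int, btype: int) -> None:
    if count < 15:
        out.append((count << 4) | btype)
    else:
        out.append((15 << 4) | btype)
        encode_typed(out, [count])


def _int_width(values) -> int:
    lo = min(values, default=0)
    hi = max(values, default=0)
    for bt in (BT_INT8, BT_INT16, BT_INT32):
        a, b = _INT_RANGE[bt]
        if a <= lo and hi <= b:
            return bt
    raise FormatError(f"integer {lo}/{hi} out of 32-bit BCF range")


def encode_typed(out: bytearray, values, btype: int | None = None) -> None:
    """Append one typed vector to ``out``.

    ``values`` may be a ``bytes``/``str`` (char vector), a list of ints
    (missing ``None`` and padding :data:`EOV` allowed), or floats.  When
    ``btype`` is omitted the smallest width holding every concrete value
    is chosen.
    """
    if isinstance(values, str):
        values = values.encode()
    if isinstance(values, (bytes, bytearray)):
        _enc_size(out, len(values), BT_CHAR)
        out.extend(values)
        return
    values = list(values)
    if not values:
        out.append(BT_NULL)
        return
    if btype is None:
        if any(isinstance(v, float) for v in values):
            btype = BT_FLOAT
        else:
            concrete = [v for v in values if v is not None and v is not EOV]
            btype = _int_width(concrete)
    _enc_size(out, len(values), btype)
    if btype == BT_FLOAT:
        for v in values:
            if v is None:
                out.extend(struct.pack("<I", FLOAT_MISSING_BITS))
            elif v is EOV:
                out.extend(struct.pack("<I", FLOAT_EOV_BITS))
            else:
                out.extend(struct.pack("<f", v))
    else:
        fmt = _INT_FMT[btype]
        for v in values:
            if v is None:
                v = INT_MISSING[btype]
            elif v is EOV:
                v = INT_EOV[btype]
            out.extend(struct.pack(fmt, v))


def decode_typed(data: bytes, offset: int = 0):
    """Decode one typed vector; returns ``(values, btype, consumed)``.

    Char vectors come back as ``str``; integer/float vectors as lists with
    ``None`` for missing and :data:`EOV` for end-of-vector padding.
    """
    start = offset
    if offset >= len(data):
        raise FormatError("truncated typed value")
    desc = data[offset]
    offset += 1
    btype = desc & 0x0F
    count = desc >> 4
    if count == 15:
        counts, _, used = decode_typed(data, offset)
        count = counts[0]
        offset += used
    if btype == BT_NULL:
        return [], BT_NULL, offset - start
    if btype == BT_CHAR:
        if offset + count > len(data):
            raise FormatError("truncated char vector")
        return data[offset : offset + count].decode("utf-8", "replace"), btype, offset - start + count
    if btype == BT_FLOAT:
        vals: list = []
        if offset + 4 * count > len(data):
            raise FormatError("truncated float vector")
        for i in range(count):
            bits = struct.unpack_from("<I", data, offset + 4 * i)[0]
            if bits == FLOAT_MISSING_BITS:
                vals.append(None)
            elif bits == FLOAT_EOV_BITS:
                vals.append(EOV)
            else:
                vals.append(canonical_float(_bits_float(bits)))
        return vals, btype, offset - start + 4 * count
    if btype not in _INT_FMT:
        raise FormatError(f"reserved BCF type code {btype}")
    width = {BT_INT8: 1, BT_INT16: 2, BT_INT32: 4}[btype]
    if offset + width * count > len(data):
        raise FormatError("truncated integer vector")
    fmt = _INT_FMT[btype]
    vals = []
    for i in range(count):
        v = struct.unpack_from(fmt, data, offset + width * i)[0]
        if v == INT_MISSING[btype]:
            vals.append(None)
        elif v == INT_EOV[btype]:
            vals.append(EOV)
        else:
            vals.append(v)
    return vals, btype, offset - start + width * count


# ------------------------------------------------------------------ header


def bcf_header_text(header: VcfHeader) -> str:
    """Header text with explicit ``IDX=`` dictionary positions.

    BCF headers carry their dictionary explicitly so any reader
    reconstructs identical indices.  ``PASS`` is materialized (index 0).
    """
    sdict = header.string_dictionary()
    cdict = header.contig_dictionary()
    sidx = {fid: i for i, fid in enumerate(sdict)}
    cidx = {n: i for i, n in enumerate(cdict)}
    lines = [f"##fileformat={header.fileformat}"]
    lines.append(f'##FILTER=<ID=PASS,Description="All filters passed",IDX=0>')
    seen_pass = True
    for section, fid in header._order:
        if section == "contig":
            continue
        if section == "FILTER" and fid == "PASS":
            continue
        table = {"INFO": header.infos, "FORMAT": header.formats,
                 "FILTER": header.filters}[section]
        if fid not in table:
            continue
        d = table[fid]
        if section == "FILTER":
            lines.append(
                f'##FILTER=<ID={d.id},Description="{d.description}",IDX={sidx[fid]}>'
            )
        else:
            extra = "".join(f",{k}={v}" for k, v in d.extra)
            lines.append(
                f"##{section}=<ID={d.id},Number={d.number},Type={d.type},"
                f'Description="{d.description}"{extra},IDX={sidx[fid]}>'
            )
    for name in header.contigs:
        length = header.contigs[name]
        attrs = f"ID={name}" + (f",length={length}" if length is not None else "")
        lines.append(f"##contig=<{attrs},IDX={cidx[name]}>")
    lines.extend(header.extra_lines)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if header.samples:
        cols += "\tFORMAT\t" + "\t".join(header.samples)
    lines.append(cols)
    return "\n".join(lines) + "\n"


def write_bcf_header(out, header: VcfHeader) -> None:
    """Write magic + length-prefixed, NUL-terminated header text."""
    text = bcf_header_text(header).encode() + b"\x00"
    out.write(MAGIC)
    out.write(struct.pack("<I", len(text)))
    out.write(text)


def read_bcf_header(stream) -> VcfHeader:
    """Read and parse the header of an (uncompressed) BCF body stream."""
    magic = stream.read(5)
    if magic[:3] != b"BCF":
        raise FormatError(f"not a BCF stream: magic {magic!r}")
    if magic != MAGIC:
        if magic[3:4] == b"\x02":
            warnings.warn(
                f"BCF version 2.{magic[4]} input; reading as 2.2 best-effort"
            )
        else:
            raise FormatError(f"unsupported BCF version in magic {magic!r}")
    (l_text,) = struct.unpack("<I", stream.read(4))
    text = stream.read(l_text).rstrip(b"\x00").decode()
    return VcfHeader.parse(text.splitlines())


# ----------------------------------------------------------------- records


@dataclass
class _Dicts:
    sidx: dict[str, int]
    sdict: list[str]
    cidx: dict[str, int]
    cdict: list[str]


def _dicts(header: VcfHeader) -> _Dicts:
    sdict = header.string_dictionary()
    cdict = header.contig_dictionary()
    return _Dicts(
        {fid: i for i, fid in enumerate(sdict)}, sdict,
        {n: i for i, n in enumerate(cdict)}, cdict,
    )


def _pack_gt(g: Genotype) -> list[int]:
    out = []
    for i, a in enumerate(g.alleles):
        phase = 0 if i == 0 else int(g.phased[i - 1])
        out.append(0 | phase if a is None else ((a + 1) << 1) | phase)
    return out


def _unpack_gt(vals: list) -> Genotype:
    alleles: list[int | None] = []
    phased: list[bool] = []
    for i, v in enumerate(vals):
        if v is EOV:
            break
        if v is None:
            v = 0  # defensive: missing int where 0 expected
        allele = (v >> 1) - 1
        alleles.append(None if allele < 0 else allele)
        if i > 0:
            phased.append(bool(v & 1))
    if not alleles:
        alleles, phased = [None], []
    return Genotype(tuple(alleles), tuple(phased))


def encode_record(record: VcfRecord, header: VcfHeader, dicts: _Dicts | None = None) -> bytes:
    """Encode one record as ``l_shared l_indiv shared indiv``."""
    d = dicts or _dicts(header)
    if record.chrom not in d.cidx:
        raise DictionaryError(f"contig {record.chrom!r} not in header dictionary")
    shared = bytearray()
    shared.extend(struct.pack("<i", d.cidx[record.chrom]))
    shared.extend(struct.pack("<i", record.pos - 1))
    shared.extend(struct.pack("<i", record.end - record.pos + 1))
    if record.qual is None:
        shared.extend(struct.pack("<I", FLOAT_MISSING_BITS))
    else:
        shared.extend(struct.pack("<f", record.qual))
    info = record.info
    shared.extend(struct.pack("<I", (record.n_allele << 16) | len(info)))
    n_fmt = len(record.format_keys)
    n_sample = record.n_samples
    shared.extend(struct.pack("<I", (n_fmt << 24) | n_sample))
    encode_typed(shared, record.id if record.id is not None else b"")
    encode_typed(shared, record.ref)
    for alt in record.alts:
        encode_typed(shared, alt)
    if record.filters is None:
        shared.append(BT_NULL)
    else:
        idxs = []
        for f in record.filters:
            if f not in d.sidx:
                raise DictionaryError(f"FILTER id {f!r} not in header dictionary")
            idxs.append(d.sidx[f])
        encode_typed(shared, idxs)
    for k, v in info.items():
        if k not in d.sidx:
            raise DictionaryError(f"INFO id {k!r} not in header dictionary")
        encode_typed(shared, [d.sidx[k]])
        fdef = header.infos.get(k)
        if v is True and (fdef is None or fdef.type == "Flag"):
            shared.append(BT_NULL)
        elif fdef is not None and fdef.type in ("String", "Character"):
            text = v if isinstance(v, str) else ",".join(map(str, v))
            encode_typed(shared, text)
        elif fdef is not None and fdef.type == "Float":
            vals = [float(x) if x is not None else None
                    for x in (v if isinstance(v, tuple) else (v,))]
            encode_typed(shared, vals, BT_FLOAT)
        else:
            vals = list(v) if isinstance(v, tuple) else [v]
            encode_typed(shared, vals)

    indiv = bytearray()
    if n_sample:
        sample_values = record.sample_values
        for k in record.format_keys:
            if k not in d.sidx:
                raise DictionaryError(f"FORMAT id {k!r} not in header dictionary")
            encode_typed(indiv, [d.sidx[k]])
            fdef = header.formats.get(k)
            if k == "GT":
                packed = [
                    _pack_gt(sv[k] if isinstance(sv.get(k), Genotype)
                             else Genotype((None,), ()))
                    for sv in sample_values
                ]
                width = max((len(p) for p in packed), default=1)
                flat: list = []
                for p in packed:
                    flat.extend(p + [EOV] * (width - len(p)))
                bt = _int_width([x for x in flat if x is not EOV])
                _enc_size(indiv, width, bt)
                fmt = _INT_FMT[bt]
                for x in flat:
                    indiv.extend(struct.pack(fmt, INT_EOV[bt] if x is EOV else x))
            elif fdef is not None and fdef.type in ("String", "Character"):
                texts = []
                for sv in sample_values:
                    v = sv.get(k)
                    texts.append("." if v is None else
                                 (v if isinstance(v, str) else ",".join(map(str, v))))
                width = max((len(t.encode()) for t in texts), default=1) or 1
                _enc_size(indiv, width, BT_CHAR)
                for t in texts:
                    b = t.encode()
                    indiv.extend(b + b"\x00" * (width - len(b)))
            else:
                is_float = fdef is not None and fdef.type == "Float"
                vecs = []
                for sv in sample_values:
                    v = sv.get(k)
                    if v is None:
                        vecs.append([None])
                    elif isinstance(v, tuple):
                        vecs.append(list(v))
                    else:
                        vecs.append([v])
                width = max((len(x) for x in vecs), default=1)
                flat = []
                for x in vecs:
                    flat.extend(x + [EOV] * (width - len(x)))
                if is_float:
                    bt = BT_FLOAT
                else:
                    concrete = [x for x in flat if x is not None and x is not EOV]
                    bt = _int_width(concrete)
                _enc_size(indiv, width, bt)
                if bt == BT_FLOAT:
                    for x in flat:
                        if x is None:
                            indiv.extend(struct.pack("<I", FLOAT_MISSING_BITS))
                        elif x is EOV:
                            indiv.extend(struct.pack("<I", FLOAT_EOV_BITS))
                        else:
                            indiv.extend(struct.pack("<f", float(x)))
                else:
                    fmt = _INT_FMT[bt]
                    for x in flat:
                        if x is None:
                            x = INT_MISSING[bt]
                        elif x is EOV:
                            x = INT_EOV[bt]
                        indiv.extend(struct.pack(fmt, x))
    return (
        struct.pack("<II", len(shared), len(indiv)) + bytes(shared) + bytes(indiv)
    )


def decode_record(data: bytes, header: VcfHeader, dicts: _Dicts | None = None,
                  offset: int = 0) -> tuple[VcfRecord, int]:
    """Decode one record block; returns ``(record, bytes_consumed)``."""
    d = dicts or _dicts(header)
    if offset + 8 > len(data):
        raise FormatError("truncated BCF record block")
    l_shared, l_indiv = struct.unpack_from("<II", data, offset)
    base = offset + 8
    if base + l_shared + l_indiv > len(data):
        raise FormatError("truncated BCF record payload")
    contig_i, pos0, rlen = struct.unpack_from("<iii", data, base)
    (qual_bits,) = struct.unpack_from("<I", data, base + 12)
    (na_ni,) = struct.unpack_from("<I", data, base + 16)
    (nf_ns,) = struct.unpack_from("<I", data, base + 20)
    n_allele, n_info = na_ni >> 16, na_ni & 0xFFFF
    n_fmt, n_sample = nf_ns >> 24, nf_ns & 0xFFFFFF
    if not (0 <= contig_i < len(d.cdict)):
        raise FormatError(f"BCF contig index {contig_i} outside dictionary")
    if n_sample != len(header.samples):
        raise FormatError(
            f"BCF record carries {n_sample} samples, header declares "
            f"{len(header.samples)}"
        )
    pos = base + 24
    idv, _, used = decode_typed(data, pos)
    pos += used
    rid = idv if isinstance(idv, str) and idv else None
    alleles = []
    for _ in range(max(n_allele, 1)):
        a, _, used = decode_typed(data, pos)
        pos += used
        alleles.append(a if isinstance(a, str) else "")
    fvals, ftype, used = decode_typed(data, pos)
    pos += used
    if ftype == BT_NULL:
        filters = None
    else:
        filters = [d.sdict[i] for i in fvals]
    info: dict = {}
    for _ in range(n_info):
        kv, _, used = decode_typed(data, pos)
        pos += used
        key = d.sdict[kv[0]]
        fdef = header.infos.get(key)
        vv, vtype, used = decode_typed(data, pos)
        pos += used
        if vtype == BT_NULL:
            info[key] = True
        elif vtype == BT_CHAR:
            if fdef is not None and fdef.number not in (0, 1, ".") and "," in vv:
                info[key] = tuple(vv.split(","))
            else:
                info[key] = vv
        else:
            vv = [x for x in vv if x is not EOV]
            if fdef is not None and fdef.number in (0, 1):
                info[key] = vv[0] if vv else None
            else:
                info[key] = tuple(vv)
    qual = None if qual_bits == FLOAT_MISSING_BITS else canonical_float(
        _bits_float(qual_bits)
    )

    format_keys: list[str] = []
    sample_values: list[dict] = [dict() for _ in range(n_sample)]
    pos = offset + 8 + l_shared
    for _ in range(n_fmt):
        kv, _, used = decode_typed(data, pos)
        pos += used
        key = d.sdict[kv[0]]
        format_keys.append(key)
        fdef = header.formats.get(key)
        desc = data[pos]
        btype = desc & 0x0F
        count = desc >> 4
        hdr_used = 1
        if count == 15:
            counts, _, u2 = decode_typed(data, pos + 1)
            count = counts[0]
            hdr_used += u2
        pos += hdr_used
        if btype == BT_CHAR:
            for si in range(n_sample):
                raw = data[pos + si * count : pos + (si + 1) * count]
                text = raw.rstrip(b"\x00").decode("utf-8", "replace")
                v = None if text in (".", "") else text
                if key == "GT":
                    from .record import parse_genotype
                    v = parse_genotype(text or ".")
                sample_values[si][key] = v
            pos += count * n_sample
        else:
            width = {BT_INT8: 1, BT_INT16: 2, BT_INT32: 4, BT_FLOAT: 4}[btype]
            fake = bytearray()
            _enc_size(fake, count, btype)
            for si in range(n_sample):
                chunk = bytes(fake) + data[pos + si * count * width :
                                           pos + (si + 1) * count * width]
                vals, _, _ = decode_typed(chunk, 0)
                if key == "GT":
                    sample_values[si][key] = _unpack_gt(vals)
                else:
                    vals = [x for x in vals if x is not EOV]
                    if all(v is None for v in vals):
                        sample_values[si][key] = None
                    elif fdef is not None and fdef.number in (0, 1):
                        sample_values[si][key] = vals[0]
                    else:
                        sample_values[si][key] = tuple(vals)
            pos += count * width * n_sample

    rec = VcfRecord(
        header,
        chrom=d.cdict[contig_i],
        pos=pos0 + 1,
        ref=alleles[0] if alleles else "N",
        alts=alleles[1:],
        id=rid,
        qual=qual,
        filters=filters,
        info=info,
        format_keys=format_keys,
        sample_values=sample_values,
    )
    return rec, 8 + l_shared + l_indiv
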