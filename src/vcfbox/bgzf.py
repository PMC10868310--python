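"""Blocked gzip (BGZF) compression with virtual-offset random access.

BGZF is a restriction of gzip: the stream is a series of independent gzip
members ("blocks"), each at most 64 KiB compressed, each carrying its own
compressed size in a ``BC`` extra-field.  Because every block can be
decompressed in isolation, a 64-bit *virtual offset* — compressed byte
offset of a block packed with an offset into its uncompressed payload —
addresses any byte of the logical stream, which is what makes tabix-style
random access into compressed VCF possible.  Any ordinary multi-member
gzip reader can still decompress the concatenation.

The writer buffers at most one block of payload; the reader caches exactly
one decompressed block, so both ends run in constant memory.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import BinaryIO

from .errors import BgzfError, CorruptionError, PlainGzipError, UsageError

#: Maximum uncompressed payload per block.  Chosen 256 bytes below 2**16 so
#: the compressed member (payload + gzip framing, even for incompressible
#: input at level 0) always fits the 16-bit BSIZE field.
MAX_BLOCK_PAYLOAD = 65280

#: The canonical 28-byte empty block terminating every BGZF file.
BGZF_EOF = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)

_HEADER = struct.Struct("<4BI2BH")  # magic1 magic2 CM FLG MTIME XFL OS XLEN
_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True, order=True)
class VirtualOffset:
    """Position in a BGZF stream: ``coffset << 16 | uoffset``.

    ``coffset`` is the file offset of the first byte of a compressed block;
    ``uoffset`` the offset within that block's decompressed payload.  The
    packed integer orders lexicographically in ``(coffset, uoffset)``.
    """

    coffset: int
    uoffset: int

    def __post_init__(self) -> None:
        if self.coffset < 0 or not (0 <= self.uoffset <= 0xFFFF):
            raise ValueError(f"invalid virtual offset ({self.coffset}, {self.uoffset})")

    @property
    def packed(self) -> int:
        return (self.coffset << 16) | self.uoffset

    @classmethod
    def from_packed(cls, packed: int) -> "VirtualOffset":
        return cls(packed >> 16, packed & 0xFFFF)

    def __int__(self) -> int:
        return self.packed

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"VirtualOffset({self.coffset}, {self.uoffset})"


def compress_block(payload: bytes, level: int = 6) -> bytes:
    """Compress one payload into a complete BGZF gzip member.

    ``level`` 0 emits stored (uncompressed) deflate blocks.  The empty
    payload compresses to the canonical end-of-file marker.
    """
    if len(payload) > MAX_BLOCK_PAYLOAD:
        raise ValueError(
            f"BGZF payload of {len(payload)} bytes exceeds the "
            f"{MAX_BLOCK_PAYLOAD}-byte block limit"
        )
    compressor = zlib.compressobj(level, zlib.DEFLATED, -15)
    deflated = compressor.compress(payload) + compressor.flush()
    bsize = len(deflated) + 25  # header 12 + extra 6 + crc/isize 8 - 1
    if bsize > 0xFFFF:
        # Incompressible payload at a high level; stored blocks always fit.
        return compress_block(payload, level=0)
    header = _HEADER.pack(0x1F, 0x8B, 8, 4, 0, 0, 0xFF, 6)
    extra = b"BC" + struct.pack("<HH", 2, bsize)
    trailer = struct.pack("<II", zlib.crc32(payload), len(payload))
    return header + extra + deflated + trailer


def _parse_block_header(data: bytes, offset: int = 0) -> int:
    """Return BSIZE+1 (total member length) or raise for non-BGZF data."""
    if data[offset : offset + 2] != _GZIP_MAGIC:
        raise BgzfError("not a BGZF stream: gzip magic bytes missing")
    if len(data) < offset + 12:
        raise CorruptionError("truncated BGZF block header")
    flg = data[offset + 3]
    if not flg & 4:  # no FEXTRA -> plain gzip
        raise PlainGzipError("gzip stream without BGZF block structure")
    xlen = struct.unpack_from("<H", data, offset + 10)[0]
    pos, end = offset + 12, offset + 12 + xlen
    if len(data) < end:
        raise CorruptionError("truncated BGZF extra field")
    while pos + 4 <= end:
        si1, si2, slen = data[pos], data[pos + 1], struct.unpack_from("<H", data, pos + 2)[0]
        if si1 == 0x42 and si2 == 0x43 and slen == 2:  # "BC"
            return struct.unpack_from("<H", data, pos + 4)[0] + 1
        pos += 4 + slen
    raise PlainGzipError("gzip member lacks the BGZF 'BC' extra field")


def decompress_block(data: bytes, offset: int = 0) -> tuple[bytes, int]:
    """Decompress one block starting at ``offset`` in ``data``.

    Returns ``(payload, bytes_consumed)``; the payload CRC is verified.
    """
    block_len = _parse_block_header(data, offset)
    if len(data) < offset + block_len:
        raise CorruptionError("truncated BGZF block body")
    flg = data[offset + 3]
    xlen = struct.unpack_from("<H", data, offset + 10)[0]
    deflate_start = offset + 12 + xlen
    if flg & ~4:  # FNAME/FCOMMENT/FHCRC never emitted by bgzip
        raise BgzfError("unsupported gzip flags in BGZF block")
    crc, isize = struct.unpack_from("<II", data, offset + block_len - 8)
    payload = zlib.decompress(
        data[deflate_start : offset + block_len - 8], -15, max(isize, 1)
    )
    if len(payload) != isize:
        raise CorruptionError("BGZF block ISIZE does not match inflated length")
    if zlib.crc32(payload) != crc:
        raise CorruptionError("BGZF block CRC mismatch")
    return payload, block_len


def is_bgzf(prefix: bytes) -> bool:
    """True iff ``prefix`` (>= 18 bytes) begins a BGZF block.

    Checks gzip magic, the FEXTRA flag, and a leading ``BC`` extra
    sub-field — the only extra-field layout bgzip ever emits, so 18 bytes
    suffice.
    """
    if len(prefix) < 18 or prefix[:2] != _GZIP_MAGIC or prefix[2] != 8:
        return False
    if not prefix[3] & 4:
        return False
    xlen = struct.unpack_from("<H", prefix, 10)[0]
    return xlen >= 6 and prefix[12:14] == b"BC" and prefix[14:16] == b"\x02\x00"


class BgzfWriter:
    """Streaming BGZF writer over a binary file object.

    Payload is buffered until a full block's worth is available; ``close``
    flushes the tail and appends the end-of-file marker exactly once.
    """

    def __init__(self, fileobj: BinaryIO, level: int = 6):
        self._fh = fileobj
        self._level = level
        self._buffer = bytearray()
        self._coffset = 0
        self._closed = False

    def write(self, data: bytes) -> int:
        if self._closed:
            raise UsageError("write after close on BGZF writer")
        self._buffer.extend(data)
        while len(self._buffer) >= MAX_BLOCK_PAYLOAD:
            self._flush_block(MAX_BLOCK_PAYLOAD)
        return len(data)

    def _flush_block(self, size: int) -> None:
        chunk = bytes(self._buffer[:size])
        del self._buffer[:size]
        member = compress_block(chunk, self._level)
        self._fh.write(member)
        self._coffset += len(member)

    def flush(self) -> None:
        """Flush buffered payload as a (possibly short) block."""
        if self._buffer:
            self._flush_block(len(self._buffer))
        self._fh.flush()

    def tell(self) -> VirtualOffset:
        return VirtualOffset(self._coffset, len(self._buffer))

    def close(self) -> None:
        if self._closed:
            return
        self.flush()
        self._fh.write(BGZF_EOF)
        self._fh.flush()
        self._closed = True

    def __enter__(self) -> "BgzfWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class BgzfReader:
    """Streaming BGZF reader with ``seek``/``tell`` virtual offsets.

    Exactly one decompressed block is cached at a time.  ``seek`` targets
    must be block boundaries recorded by ``tell`` (or stored in an index);
    seeking into the middle of a block surfaces as a corruption error on
    the next read.
    """

    def __init__(self, fileobj: BinaryIO):
        self._fh = fileobj
        self._block = b""
        self._block_coffset = 0
        self._next_coffset = 0
        self._within = 0
        self._eof = False

    def _load_block(self) -> bool:
        """Read the block at ``self._next_coffset``; False at end of file."""
        self._fh.seek(self._next_coffset)
        head = self._fh.read(12)
        if not head:
            self._eof = True
            self._block = b""
            self._block_coffset = self._next_coffset
            self._within = 0
            return False
        if len(head) < 12:
            raise CorruptionError("truncated BGZF block header")
        xlen = struct.unpack_from("<H", head, 10)[0] if head[3] & 4 else 0
        head += self._fh.read(xlen)
        block_len = _parse_block_header(head, 0)
        rest = self._fh.read(block_len - len(head))
        payload, _ = decompress_block(head + rest, 0)
        self._block = payload
        self._block_coffset = self._next_coffset
        self._next_coffset += block_len
        self._within = 0
        # Empty blocks (the EOF marker, or flushed-empty blocks) are
        # transparent: skip to the next member.
        if not payload:
            return self._load_block()
        return True

    def _ensure_data(self) -> bool:
        while self._within >= len(self._block):
            if self._eof or not self._load_block():
                return False
        return True

    def read(self, size: int = -1) -> bytes:
        out = bytearray()
        while size < 0 or len(out) < size:
            if not self._ensure_data():
                break
            take = len(self._block) - self._within
            if size >= 0:
                take = min(take, size - len(out))
            out += self._block[self._within : self._within + take]
            self._within += take
        return bytes(out)

    def readline(self) -> bytes:
        out = bytearray()
        while self._ensure_data():
            nl = self._block.find(b"\n", self._within)
            if nl >= 0:
                out += self._block[self._within : nl + 1]
                self._within = nl + 1
                return bytes(out)
            out += self._block[self._within :]
            self._within = len(self._block)
        return bytes(out)

    def tell(self) -> VirtualOffset:
        if self._within == len(self._block) and not self._eof:
            # Normalize end-of-block to start-of-next-block so offsets
            # recorded between records are monotone and seekable.
            return VirtualOffset(self._next_coffset, 0)
        return VirtualOffset(self._block_coffset, self._within)

    def seek(self, voffset: VirtualOffset | int) -> None:
        if isinstance(voffset, int):
            voffset = VirtualOffset.from_packed(voffset)
        self._eof = False
        self._block = b""
        self._next_coffset = voffset.coffset
        self._within = 0
        if not self._load_block():
            if voffset.uoffset:
                raise CorruptionError("seek past end of BGZF stream")
            return
        if voffset.uoffset > len(self._block):
            raise CorruptionError(
                f"virtual offset {voffset!r} points beyond its block payload"
            )
        self._within = voffset.uoffset

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "BgzfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
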