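"""Unified reader/writer facade over the text and binary codecs.

``VcfReader`` sniffs the container (plain VCF text, BGZF-compressed VCF,
plain gzip VCF, or BCF), parses the header, and iterates records one at a
time — the streaming contract: at most one decoded record is resident in
the reader at any moment.  Optional constraints restrict iteration to a
genomic region (random access through a ``.tbi`` sidecar, built on the
fly when missing) and to a subset of samples in a caller-chosen order;
FORMAT values of unrequested samples are dropped before records surface.

``VcfWriter`` emits any of the three on-disk forms and guarantees that
its output re-opens cleanly: BGZF modes end with the canonical
end-of-file marker, BCF headers carry their dictionary explicitly.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import sys
from dataclasses import dataclass
from typing import Iterator

from . import bcf, tabix
from .bgzf import BgzfReader, BgzfWriter, is_bgzf
from .errors import (
    FormatError,
    UnknownSampleError,
    UsageError,
    ValidationError,
    VcfboxError,
)
from .header import VcfHeader
from .record import VcfRecord, parse_record, validate_record

logger = logging.getLogger("vcfbox")

MODES = ("vcf-plain", "vcf-bgzf", "bcf")


def sniff_format(prefix: bytes) -> str:
    """Classify the first bytes: vcf-plain | vcf-bgzf | vcf-gzip | bcf."""
    if prefix[:3] == b"BCF":
        return "bcf"  # raw, uncompressed BCF body
    if is_bgzf(prefix[:18].ljust(18, b"\x00")):
        return "bcf" if _bgzf_payload_prefix(prefix)[:3] == b"BCF" else "vcf-bgzf"
    if prefix[:2] == b"\x1f\x8b":
        return "vcf-gzip"
    try:
        text = prefix.decode("utf-8")
    except UnicodeDecodeError:
        raise FormatError("unrecognized file format: binary data that is "
                          "neither BGZF, gzip nor BCF") from None
    if text.startswith("##") or text.startswith("#CHROM") or not text:
        return "vcf-plain"
    raise FormatError("unrecognized file format: text without a VCF header")


def _bgzf_payload_prefix(prefix: bytes) -> bytes:
    from .bgzf import decompress_block

    try:
        payload, _ = decompress_block(prefix, 0)
        return payload[:8]
    except VcfboxError:
        # first block truncated in the sniff buffer: inflate what we have
        import zlib

        xlen = int.from_bytes(prefix[10:12], "little")
        d = zlib.decompressobj(-15)
        try:
            return d.decompress(prefix[12 + xlen:], 8)
        except zlib.error:
            return b""


def parse_sample_spec(spec, header_samples: list[str]) -> list[str]:
    """Resolve a sample constraint into an ordered include list.

    ``spec`` may be a list of names, a comma string, or a ``^``-prefixed
    exclusion (complement, header order preserved).
    """
    if isinstance(spec, str):
        if spec.startswith("^"):
            excluded = spec[1:].split(",")
            unknown = [s for s in excluded if s not in header_samples]
            if unknown:
                raise UnknownSampleError(f"unknown sample name(s): {unknown}")
            return [s for s in header_samples if s not in excluded]
        spec = spec.split(",")
    names = list(spec)
    unknown = [s for s in names if s not in header_samples]
    if unknown:
        raise UnknownSampleError(f"unknown sample name(s): {unknown}")
    return names


class VcfReader:
    """Streaming reader with optional region and sample constraints."""

    def __init__(
        self,
        path: str,
        region: str | tabix.Region | None = None,
        samples=None,
        strict: bool = False,
        index_path: str | None = None,
    ):
        self.path = path
        self.strict = strict
        self._closed = False
        if path == "-":
            raw = sys.stdin.buffer.read()
            self._fh: io.IOBase = io.BytesIO(raw)
        else:
            if path.startswith(("http://", "https://", "ftp://", "s3://")):
                raise VcfboxError(
                    "remote URLs are not supported; download the file first"
                )
            self._fh = open(path, "rb")
        prefix = self._fh.read(8192)
        self._fh.seek(0)
        self.format = sniff_format(prefix)
        self._bcf_dicts = None
        if self.format == "bcf":
            if prefix[:3] == b"BCF":
                self._stream = self._fh  # raw body
            else:
                self._stream = BgzfReader(self._fh)
            self.header = bcf.read_bcf_header(self._stream)
            self._bcf_dicts = bcf._dicts(self.header)
        elif self.format == "vcf-bgzf":
            self._stream = BgzfReader(self._fh)
            self.header = self._read_text_header(self._stream)
        elif self.format == "vcf-gzip":
            self._stream = gzip.GzipFile(fileobj=self._fh)
            self.header = self._read_text_header(self._stream)
        else:
            self._stream = self._fh
            self.header = self._read_text_header(self._stream)

        # sample projection
        if samples is not None:
            self.samples = parse_sample_spec(samples, self.header.samples)
        else:
            self.samples = list(self.header.samples)
        self._projected = self.samples != self.header.samples
        self._out_header = (
            self.header.subset_samples(self.samples) if self._projected
            else self.header
        )
        self._sample_idx = [self.header.samples.index(s) for s in self.samples]

        # region constraint
        if isinstance(region, str):
            region = tabix.Region.parse(region)
        self.region = region
        self._line_iter: Iterator[str] | None = None
        self._line_no = 0
        self._n_yielded = 0
        self.resident_record: VcfRecord | None = None
        if region is not None:
            self._setup_region(index_path)

    # ------------------------------------------------------------- internals

    @staticmethod
    def _read_text_header(stream) -> VcfHeader:
        lines = []
        while True:
            raw = stream.readline()
            if not raw:
                break
            line = raw.decode("utf-8") if isinstance(raw, bytes) else raw
            lines.append(line)
            if line.startswith("#CHROM"):
                break
            if not line.startswith("#"):
                raise FormatError("VCF body encountered before the #CHROM line")
        return VcfHeader.parse(lines)

    def _setup_region(self, index_path: str | None) -> None:
        if self.format == "vcf-bgzf" and self.path != "-":
            tbi = index_path or self.path + ".tbi"
            if os.path.exists(tbi):
                index = tabix.read_tbi(tbi)
            else:
                logger.info("no index at %s; building one on the fly", tbi)
                with open(self.path, "rb") as fh:
                    index = tabix.build_index(BgzfReader(fh))
            fetch_bgzf = BgzfReader(open(self.path, "rb"))
            self._line_iter = tabix.fetch_lines(fetch_bgzf, index, self.region)
        else:
            if self.format != "vcf-bgzf":
                logger.info(
                    "region on %s input: falling back to a linear scan", self.format
                )
            self._line_iter = None  # linear scan with overlap filter

    # ------------------------------------------------------------- iteration

    def __iter__(self) -> "VcfReader":
        return self

    def __next__(self) -> VcfRecord:
        rec = self._next_raw()
        while rec is not None and self.region is not None and self._line_iter is None:
            # linear-scan region filter
            if rec.chrom == self.region.contig and self.region.overlaps(
                rec.pos - 1, rec.end
            ):
                break
            rec = self._next_raw()
        if rec is None:
            raise StopIteration
        if self.strict:
            violations = validate_record(self.header, rec)
            if violations:
                raise ValidationError("; ".join(violations))
        rec = self._project(rec)
        self.resident_record = rec
        self._n_yielded += 1
        return rec

    def _next_raw(self) -> VcfRecord | None:
        if self.format == "bcf":
            head = self._stream.read(8)
            if not head:
                return None
            if len(head) < 8:
                raise FormatError("truncated BCF record block")
            l_shared = int.from_bytes(head[:4], "little")
            l_indiv = int.from_bytes(head[4:8], "little")
            body = self._stream.read(l_shared + l_indiv)
            rec, _ = bcf.decode_record(head + body, self.header, self._bcf_dicts)
            return rec
        if self._line_iter is not None:
            line = next(self._line_iter, None)
            if line is None:
                return None
            return parse_record(line, self.header)
        while True:
            raw = self._stream.readline()
            if not raw:
                return None
            self._line_no += 1
            line = raw.decode("utf-8") if isinstance(raw, bytes) else raw
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            return parse_record(line, self.header, self._line_no)

    def _project(self, rec: VcfRecord) -> VcfRecord:
        if not self._projected:
            return rec
        out = VcfRecord.__new__(VcfRecord)
        out.header = self._out_header
        out.chrom, out.pos, out.id = rec.chrom, rec.pos, rec.id
        out.ref, out.alts = rec.ref, list(rec.alts)
        out.qual, out.filters = rec.qual, rec.filters
        out.format_keys = list(rec.format_keys)
        out._info_raw, out._info = rec._info_raw, rec._info
        out.line_number = rec.line_number
        if rec._samples_raw is not None and rec._sample_values is None:
            out._samples_raw = [rec._samples_raw[i] for i in self._sample_idx]
            out._sample_values = None
        else:
            out._samples_raw = None
            out._sample_values = [rec.sample_values[i] for i in self._sample_idx]
        return out

    # ----------------------------------------------------------------- misc

    @property
    def out_header(self) -> VcfHeader:
        """The header seen by consumers (sample axis already projected)."""
        return self._out_header

    def records(self) -> Iterator[VcfRecord]:
        return iter(self)

    def close(self) -> None:
        if not self._closed:
            self._fh.close()
            self._closed = True

    def __enter__(self) -> "VcfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _infer_mode(path: str) -> str:
    if path.endswith(".bcf"):
        return "bcf"
    if path.endswith((".vcf.gz", ".vcf.bgz", ".gz")):
        return "vcf-bgzf"
    return "vcf-plain"


@dataclass
class WriterConfig:
    path: str
    mode: str | None = None
    level: int = 6


class VcfWriter:
    """Writes VCF text, BGZF-compressed VCF, or BCF."""

    def __init__(self, path: str, header: VcfHeader, mode: str | None = None,
                 level: int = 6):
        self.path = path
        self.header = header
        self.mode = mode or _infer_mode(path)
        if self.mode not in MODES:
            raise VcfboxError(f"unknown writer mode {self.mode!r}")
        self._closed = False
        self._n_written = 0
        if path == "-":
            self._fh = sys.stdout.buffer
            self._owns_fh = False
        else:
            self._fh = open(path, "wb")
            self._owns_fh = True
        if self.mode == "vcf-plain":
            self._sink = self._fh
            self._sink.write(header.to_text().encode())
        elif self.mode == "vcf-bgzf":
            self._sink = BgzfWriter(self._fh, level)
            self._sink.write(header.to_text().encode())
        else:
            self._sink = BgzfWriter(self._fh, level)
            buf = io.BytesIO()
            bcf.write_bcf_header(buf, header)
            self._sink.write(buf.getvalue())
            self._dicts = bcf._dicts(header)

    def write_record(self, record: VcfRecord) -> None:
        if self._closed:
            raise UsageError("write after close on VCF writer")
        n = (
            len(record._samples_raw)
            if record._samples_raw is not None and record._sample_values is None
            else len(record.sample_values)
        )
        if n != len(self.header.samples):
            raise VcfboxError(
                f"record carries {n} samples, writer header declares "
                f"{len(self.header.samples)}"
            )
        if self.mode == "bcf":
            self._sink.write(bcf.encode_record(record, self.header, self._dicts))
        else:
            self._sink.write((record.to_line() + "\n").encode())
        self._n_written += 1

    def close(self) -> None:
        if self._closed:
            return
        if isinstance(self._sink, BgzfWriter):
            self._sink.close()
        elif self._owns_fh:
            self._fh.flush()
        if self._owns_fh:
            self._fh.close()
        self._closed = True

    def __enter__(self) -> "VcfWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def convert(src: str, dst: str, mode: str | None = None,
            region: str | None = None, samples=None, level: int = 6) -> int:
    """Copy ``src`` to ``dst`` across any format pair; returns record count."""
    with VcfReader(src, region=region, samples=samples) as reader:
        with VcfWriter(dst, reader.out_header, mode=mode, level=level) as writer:
            n = 0
            for rec in reader:
                writer.write_record(rec)
                n += 1
    return n


def read_all(path: str, **kwargs) -> tuple[VcfHeader, list[VcfRecord]]:
    """Two-step convenience: load the whole file into memory at once."""
    with VcfReader(path, **kwargs) as reader:
        records = list(reader)
        return reader.out_header, records
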