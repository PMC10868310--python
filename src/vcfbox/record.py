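"""One variant site: fixed fields, INFO, per-sample FORMAT values, genotypes.

Records parse lazily: the TAB-split of a body line keeps INFO and the
per-sample columns as raw strings until they are first accessed, so a
streaming pass that only touches CHROM/POS/QUAL (or only GT) never pays
for full decoding.  ``format_record(parse_record(x)) == x`` up to numeric
canonicalization (shortest round-trip decimals; ``.`` stays missing and
is never conflated with 0 or PASS).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, NoGenotypeError, VcfboxError
from .header import VcfHeader

MISSING = None

_BASES = frozenset("ACGTNacgtn")


class VariantType(enum.Enum):
    SNP = "SNP"
    MNP = "MNP"
    INDEL = "INDEL"
    SV = "SV"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Genotype:
    """A parsed GT call: allele indices (``None`` = missing) and phasing.

    ``phased[i]`` says whether the separator *before* allele ``i+1`` was
    ``|``; ploidy is simply the number of alleles written.
    """

    alleles: tuple[int | None, ...]
    phased: tuple[bool, ...]

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    def __str__(self) -> str:
        parts = ["." if self.alleles[0] is None else str(self.alleles[0])]
        for a, ph in zip(self.alleles[1:], self.phased):
            parts.append(("|" if ph else "/") + ("." if a is None else str(a)))
        return "".join(parts)


def parse_genotype(token: str) -> Genotype:
    """Parse a GT token like ``0|1``, ``./.``, ``1`` or ``0/1/2``."""
    alleles: list[int | None] = []
    phased: list[bool] = []
    start = 0
    for i, c in enumerate(token):
        if c in "/|":
            alleles.append(_allele(token[start:i]))
            phased.append(c == "|")
            start = i + 1
    alleles.append(_allele(token[start:]))
    return Genotype(tuple(alleles), tuple(phased))


def _allele(tok: str) -> int | None:
    if tok == "." or tok == "":
        return None
    try:
        return int(tok)
    except ValueError as exc:
        raise FormatError(f"bad allele index {tok!r} in GT") from exc


def is_het(g: Genotype) -> bool:
    """True iff diploid, both alleles called, and the two indices differ.

    Missing alleles never count; a multiallelic ``1/2`` call does (the
    two alleles differ), switchable upstream via genotype recoding if a
    biallelic-only definition is wanted.
    """
    return (
        g.ploidy == 2
        and g.alleles[0] is not None
        and g.alleles[1] is not None
        and g.alleles[0] != g.alleles[1]
    )


def _fmt_float(x: float) -> str:
    """Shortest decimal that round-trips; integral values print as integers."""
    if math.isinf(x) or math.isnan(x):
        return repr(x)
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


class VcfRecord:
    """A mutable variant record bound to a header for typing.

    Attributes mirror the VCF columns: ``chrom``, ``pos`` (1-based),
    ``id`` (None = missing), ``ref``, ``alts``, ``qual`` (float or None),
    ``filters`` (list of ids, or None when FILTER is ``.``), ``info``
    (ordered dict), ``format_keys`` and per-sample values.
    """

    __slots__ = (
        "header", "chrom", "pos", "id", "ref", "alts", "qual", "filters",
        "format_keys", "_info_raw", "_info", "_samples_raw", "_sample_values",
        "line_number",
    )

    def __init__(
        self,
        header: VcfHeader,
        chrom: str,
        pos: int,
        ref: str,
        alts: list[str],
        id: str | None = None,
        qual: float | None = None,
        filters: list[str] | None = None,
        info: dict | None = None,
        format_keys: list[str] | None = None,
        sample_values: list[dict] | None = None,
    ):
        self.header = header
        self.chrom = chrom
        self.pos = pos
        self.id = id
        self.ref = ref
        self.alts = list(alts)
        self.qual = qual
        self.filters = filters
        self.format_keys = list(format_keys or [])
        self._info_raw: str | None = None
        self._info = dict(info) if info is not None else {}
        self._samples_raw: list[str] | None = None
        self._sample_values = list(sample_values) if sample_values is not None else []
        self.line_number: int | None = None
        if self.format_keys and "GT" in self.format_keys and self.format_keys[0] != "GT":
            raise FormatError("GT, when present, must be the first FORMAT key")

    # ------------------------------------------------------------------ sizes

    @property
    def n_allele(self) -> int:
        return 1 + len(self.alts)

    @property
    def n_samples(self) -> int:
        return len(self.header.samples)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span (honors INFO END)."""
        info_end = self.info.get("END")
        span = len(self.ref)
        if info_end is not None:
            span = max(span, int(info_end) - self.pos + 1)
        return self.pos + max(span, 1) - 1

    # ------------------------------------------------------------------- INFO

    @property
    def info(self) -> dict:
        if self._info is None:
            self._info = _parse_info(self._info_raw or ".", self.header)
        return self._info

    @info.setter
    def info(self, value: dict) -> None:
        self._info = dict(value)
        self._info_raw = None

    # ---------------------------------------------------------------- samples

    @property
    def sample_values(self) -> list[dict]:
        """Per-sample mapping FORMAT id -> typed value(s); parsed on demand."""
        if self._sample_values is None:
            self._sample_values = [
                _parse_sample(raw, self.format_keys, self.header)
                for raw in (self._samples_raw or [])
            ]
        return self._sample_values

    @sample_values.setter
    def sample_values(self, value: list[dict]) -> None:
        self._sample_values = list(value)
        self._samples_raw = None

    def raw_format_strings(self, key: str) -> list[str]:
        """Fast path: the raw colon-delimited slot for ``key`` per sample."""
        if key not in self.format_keys:
            return ["."] * self.n_samples
        ki = self.format_keys.index(key)
        if self._samples_raw is not None:
            out = []
            for raw in self._samples_raw:
                parts = raw.split(":")
                out.append(parts[ki] if ki < len(parts) else ".")
            return out
        return [_format_typed(sv.get(key), "String") for sv in self.sample_values]

    # -------------------------------------------------------------- genotypes

    def genotypes(self) -> list[Genotype]:
        if "GT" not in self.format_keys:
            raise NoGenotypeError(
                f"record {self.chrom}:{self.pos} carries no GT FORMAT field"
            )
        if self._samples_raw is not None:
            return [parse_genotype(raw.split(":", 1)[0]) for raw in self._samples_raw]
        return [
            sv["GT"] if isinstance(sv.get("GT"), Genotype)
            else parse_genotype(str(sv.get("GT", ".")))
            for sv in self.sample_values
        ]

    def genotype_matrix(self, width: str = "full-int") -> np.ndarray:
        """Samples × max-ploidy allele matrix at the requested cell width.

        ``presence``: boolean carrier matrix (any called allele > 0), shape
        (n_samples,).  ``small-int``: int8 allele indices (requires
        n_allele <= 127).  ``full-int``: int32.  Missing alleles code as
        -1, ploidy padding as -2; the integer widths agree after widening.
        """
        gts = self.genotypes()
        if width == "presence":
            return np.array(
                [any(a is not None and a > 0 for a in g.alleles) for g in gts],
                dtype=bool,
            )
        if width == "small-int":
            if self.n_allele > 127:
                raise VcfboxError(
                    f"small-int genotype matrix cannot hold {self.n_allele} alleles"
                )
            dtype = np.int8
        elif width == "full-int":
            dtype = np.int32
        else:
            raise VcfboxError(f"unknown genotype width {width!r}")
        max_ploidy = max((g.ploidy for g in gts), default=0)
        mat = np.full((len(gts), max_ploidy), -2, dtype=dtype)
        for i, g in enumerate(gts):
            for j, a in enumerate(g.alleles):
                mat[i, j] = -1 if a is None else a
        return mat

    # ------------------------------------------------------------------- text

    def to_line(self) -> str:
        cols = [
            self.chrom,
            str(self.pos),
            self.id if self.id is not None else ".",
            self.ref,
            ",".join(self.alts) if self.alts else ".",
            "." if self.qual is None else _fmt_float(self.qual),
            ";".join(self.filters) if self.filters else ".",
            self._info_text(),
        ]
        if self.header.samples:
            cols.append(":".join(self.format_keys) if self.format_keys else ".")
            if self._samples_raw is not None and self._sample_values is None:
                cols.extend(self._samples_raw)
            else:
                for sv in self.sample_values:
                    cols.append(_format_sample(sv, self.format_keys))
        return "\t".join(cols)

    def _info_text(self) -> str:
        if self._info is None and self._info_raw is not None:
            return self._info_raw
        if not self.info:
            return "."
        parts = []
        for k, v in self.info.items():
            if v is True:
                parts.append(k)
            else:
                fdef = self.header.infos.get(k)
                parts.append(f"{k}={_format_typed(v, fdef.type if fdef else 'String')}")
        return ";".join(parts)

    def __repr__(self) -> str:  # pragma: no cover
        alts = ",".join(self.alts) or "."
        return f"<VcfRecord {self.chrom}:{self.pos} {self.ref}>{alts}>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VcfRecord):
            return NotImplemented
        return semantically_equal(self, other)


def semantically_equal(a: VcfRecord, b: VcfRecord) -> bool:
    """Field-level equality ignoring text-representation differences."""
    def _canon_sv(sv: dict) -> dict:
        return {k: (str(v) if isinstance(v, Genotype) else v) for k, v in sv.items()}

    qual_eq = (
        (a.qual is None and b.qual is None)
        or (a.qual is not None and b.qual is not None
            and math.isclose(a.qual, b.qual, rel_tol=1e-6, abs_tol=1e-6))
    )
    return (
        a.chrom == b.chrom and a.pos == b.pos and a.id == b.id
        and a.ref == b.ref and a.alts == b.alts and qual_eq
        and a.filters == b.filters and a.info == b.info
        and a.format_keys == b.format_keys
        and [_canon_sv(s) for s in a.sample_values]
        == [_canon_sv(s) for s in b.sample_values]
    )


# ------------------------------------------------------------------ parsing


def _parse_typed_scalar(tok: str, vtype: str):
    if tok == ".":
        return None
    if vtype == "Integer":
        return int(tok)
    if vtype == "Float":
        return float(tok)
    return tok


def _parse_typed(tok: str, vtype: str, number):
    """A FORMAT/INFO value slot: scalar for Number=1, tuple otherwise."""
    if number == 1 or number == 0:
        return _parse_typed_scalar(tok, vtype)
    if vtype in ("String", "Character") and number == ".":
        return tok  # free-text strings keep their commas
    return tuple(_parse_typed_scalar(t, vtype) for t in tok.split(","))


def _format_typed(v, vtype: str) -> str:
    if v is None:
        return "."
    if isinstance(v, Genotype):
        return str(v)
    if isinstance(v, (tuple, list)):
        return ",".join(_format_typed(x, vtype) for x in v)
    if isinstance(v, float):
        return _fmt_float(v)
    return str(v)


def _parse_info(text: str, header: VcfHeader) -> dict:
    out: dict = {}
    if text == "." or text == "":
        return out
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            fdef = header.infos.get(k)
            vtype = fdef.type if fdef else "String"
            number = fdef.number if fdef else "."
            out[k] = _parse_typed(v, vtype, number)
        else:
            out[item] = True
    return out


def _parse_sample(raw: str, format_keys: list[str], header: VcfHeader) -> dict:
    out: dict = {}
    parts = raw.split(":")
    for i, key in enumerate(format_keys):
        tok = parts[i] if i < len(parts) else "."
        if key == "GT":
            out[key] = parse_genotype(tok)
            continue
        fdef = header.formats.get(key)
        vtype = fdef.type if fdef else "String"
        number = fdef.number if fdef else "."
        if tok == ".":
            out[key] = None
        else:
            out[key] = _parse_typed(tok, vtype, number)
    return out


def _format_sample(sv: dict, format_keys: list[str]) -> str:
    if not format_keys:
        return "."
    toks = []
    for key in format_keys:
        v = sv.get(key)
        toks.append(_format_typed(v, "String"))
    # trailing missing slots may be dropped per the format grammar, but we
    # keep them for stable round-trips
    return ":".join(toks) if toks else "."


def parse_record(line: str, header: VcfHeader, line_number: int | None = None) -> VcfRecord:
    """Parse one TAB-delimited body line against ``header``."""
    fields = line.rstrip("\n").split("\t")
    n_fixed = 8
    expected = n_fixed + (1 + len(header.samples) if header.samples else 0)
    if len(fields) != expected:
        where = f" at line {line_number}" if line_number else ""
        raise FormatError(
            f"body line{where} has {len(fields)} columns; header requires {expected}"
        )
    chrom, pos_s, id_s, ref, alt_s, qual_s, filt_s, info_s = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"non-numeric POS {pos_s!r}") from exc
    if qual_s == ".":
        qual: float | None = None
    else:
        try:
            qual = float(qual_s)
        except ValueError as exc:
            raise FormatError(f"non-numeric QUAL {qual_s!r}") from exc
        if qual < 0:
            raise FormatError(f"negative QUAL {qual_s!r}")
    rec = VcfRecord.__new__(VcfRecord)
    rec.header = header
    rec.chrom = chrom
    rec.pos = pos
    rec.id = None if id_s == "." else id_s
    rec.ref = ref
    rec.alts = [] if alt_s == "." else alt_s.split(",")
    rec.qual = qual
    rec.filters = None if filt_s == "." else filt_s.split(";")
    rec._info_raw = info_s
    rec._info = None
    rec.line_number = line_number
    if header.samples:
        fmt = fields[8]
        rec.format_keys = [] if fmt == "." else fmt.split(":")
        if "GT" in rec.format_keys and rec.format_keys[0] != "GT":
            raise FormatError("GT, when present, must be the first FORMAT key")
        rec._samples_raw = fields[9:]
        rec._sample_values = None
    else:
        rec.format_keys = []
        rec._samples_raw = []
        rec._sample_values = []
    return rec


def format_record(record: VcfRecord) -> str:
    """Inverse of :func:`parse_record` up to numeric canonicalization."""
    return record.to_line()


# ------------------------------------------------------------ classification


def _alt_class(ref: str, alt: str) -> VariantType:
    if alt.startswith("<") and alt.endswith(">"):
        return VariantType.SV
    if "[" in alt or "]" in alt or alt.startswith(".") or alt.endswith("."):
        return VariantType.SV  # breakend notation
    if not alt or not all(c in _BASES for c in alt):
        return VariantType.OTHER
    if not all(c in _BASES for c in ref):
        return VariantType.OTHER
    if len(ref) == len(alt):
        return VariantType.SNP if len(ref) == 1 else VariantType.MNP
    return VariantType.INDEL


def classify_variant(record: VcfRecord) -> tuple[VariantType, bool]:
    """(variant type, multiallelic flag) for one record.

    SNP: all alleles single bases; MNP: equal lengths > 1; INDEL: sequence
    alleles of differing length; SV: any symbolic or breakend ALT; mixed
    per-alt classes collapse to OTHER.  Monoallelic (no ALT) → OTHER.
    """
    multiallelic = len(record.alts) > 1
    if not record.alts:
        return VariantType.OTHER, multiallelic
    classes = {_alt_class(record.ref, alt) for alt in record.alts}
    if VariantType.SV in classes:
        # a single symbolic allele marks the record as SV even when mixed
        kind = VariantType.SV if classes == {VariantType.SV} else VariantType.OTHER
        return kind, multiallelic
    if len(classes) == 1:
        return classes.pop(), multiallelic
    return VariantType.OTHER, multiallelic


# --------------------------------------------------------------- validation


def _expected_count(number, n_allele: int, ploidy: int = 2) -> int | None:
    if isinstance(number, int):
        return number if number > 0 else None
    if number == "A":
        return n_allele - 1
    if number == "R":
        return n_allele
    if number == "G":
        # diploid genotype count: n*(n+1)/2
        return n_allele * (n_allele + 1) // 2
    return None  # '.' unbounded


def validate_record(header: VcfHeader, record: VcfRecord) -> list[str]:
    """Advisory validation: one message per violation, empty when clean.

    Checks undeclared INFO/FORMAT/FILTER ids used in the body and
    Number=A/R/G cardinality against the record's allele count.
    """
    violations: list[str] = []
    where = f"{record.chrom}:{record.pos}"
    for fid in record.filters or []:
        if fid not in header.filters and fid != "PASS":
            violations.append(f"{where}: FILTER id {fid!r} is not declared")
    for k, v in record.info.items():
        fdef = header.infos.get(k)
        if fdef is None:
            violations.append(f"{where}: INFO id {k!r} is not declared")
            continue
        if fdef.type == "Flag":
            if v is not True:
                violations.append(f"{where}: INFO flag {k!r} carries a value")
            continue
        n = len(v) if isinstance(v, tuple) else 1
        exp = _expected_count(fdef.number, record.n_allele)
        if exp is not None and n != exp:
            violations.append(
                f"{where}: INFO {k!r} has {n} value(s), Number={fdef.number} "
                f"expects {exp} for {record.n_allele} allele(s)"
            )
    for k in record.format_keys:
        fdef = header.formats.get(k)
        if fdef is None:
            violations.append(f"{where}: FORMAT id {k!r} is not declared")
            continue
        if k == "GT":
            continue
        exp = _expected_count(fdef.number, record.n_allele)
        if exp is None:
            continue
        for si, sv in enumerate(record.sample_values):
            v = sv.get(k)
            if v is None:
                continue
            n = len(v) if isinstance(v, tuple) else 1
            if n != exp:
                violations.append(
                    f"{where}: FORMAT {k!r} sample {header.samples[si]} has "
                    f"{n} value(s), Number={fdef.number} expects {exp}"
                )
    return violations
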