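"""VCF header model: declarations, sample list, and the string dictionary.

A VCF header is not decoration: a body tag without its header declaration
violates the format, and the binary (BCF) encoding refers to INFO, FORMAT
and FILTER ids — and to contigs — purely by their dictionary index.  This
module owns both concerns: structured parsing/serialization of ``##``
lines and the shared FILTER/INFO/FORMAT string dictionary (``PASS`` is
always index 0) that the text and binary codecs use.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .errors import DuplicateIdError, FormatError, VcfboxError

_FIXED_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]

VALID_TYPES = {"Integer", "Float", "String", "Character", "Flag"}


@dataclass(frozen=True)
class FieldDef:
    """One ``##INFO``/``##FORMAT``/``##FILTER`` declaration.

    ``number`` is an int >= 0 or one of ``A`` (per alt allele), ``R`` (per
    allele incl. REF), ``G`` (per genotype), ``.`` (unbounded).  FILTER
    definitions carry only id/description.
    """

    id: str
    number: int | str = "."
    type: str = "String"
    description: str = ""
    idx: int | None = None
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.type not in VALID_TYPES:
            raise FormatError(f"unknown field Type {self.type!r} for {self.id}")
        if self.type == "Flag" and self.number != 0:
            raise FormatError(f"Flag field {self.id} must have Number=0")


def _split_structured(body: str) -> list[tuple[str, str]]:
    """Split ``ID=DP,Number=1,Description="a,b"`` respecting quotes."""
    pairs = []
    key, buf, in_quotes, i = "", [], False, 0
    state = "key"
    while i < len(body):
        c = body[i]
        if state == "key":
            if c == "=":
                key, state = "".join(buf), "value"
                buf = []
            else:
                buf.append(c)
        else:
            if c == '"':
                in_quotes = not in_quotes
                buf.append(c)
            elif c == "," and not in_quotes:
                pairs.append((key, "".join(buf)))
                buf, state = [], "key"
            else:
                buf.append(c)
        i += 1
    if state == "value":
        pairs.append((key, "".join(buf)))
    elif buf:
        raise FormatError(f"malformed structured header body: {body!r}")
    return pairs


def _unquote(v: str) -> str:
    return v[1:-1] if len(v) >= 2 and v[0] == '"' and v[-1] == '"' else v


_STRUCTURED_RE = re.compile(r"^##(?P<key>[^=]+)=<(?P<body>.*)>$")
_PLAIN_RE = re.compile(r"^##(?P<key>[^=]+)=(?P<value>.*)$")


@dataclass
class VcfHeader:
    """Declarations, samples and the BCF string dictionary."""

    fileformat: str = "VCFv4.2"
    contigs: dict[str, int | None] = field(default_factory=dict)
    infos: dict[str, FieldDef] = field(default_factory=dict)
    formats: dict[str, FieldDef] = field(default_factory=dict)
    filters: dict[str, FieldDef] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)
    #: declaration order of structured lines, (section, id) tuples
    _order: list[tuple[str, str]] = field(default_factory=list)
    #: explicit IDX= values seen while parsing (BCF headers)
    _explicit_idx: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "PASS" not in self.filters:
            self.filters["PASS"] = FieldDef("PASS", 0, "Flag", "All filters passed")
            # PASS is implicit; do not echo it unless it was declared

    # ------------------------------------------------------------------ parse

    @classmethod
    def parse(cls, lines) -> "VcfHeader":
        """Build a header from meta lines up to and including ``#CHROM``."""
        hdr = cls.__new__(cls)
        hdr.fileformat = ""
        hdr.contigs = {}
        hdr.infos, hdr.formats, hdr.filters = {}, {}, {}
        hdr.samples, hdr.extra_lines = [], []
        hdr._order, hdr._explicit_idx = [], {}
        saw_chrom = False
        for raw in lines:
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("##"):
                hdr._parse_meta(line)
            elif line.startswith("#CHROM"):
                hdr._parse_column_line(line)
                saw_chrom = True
                break
            else:
                raise FormatError(f"unexpected line in header: {line[:60]!r}")
        if not saw_chrom:
            raise FormatError("header lacks the mandatory #CHROM column line")
        if not hdr.fileformat:
            warnings.warn("missing ##fileformat line; assuming VCFv4.2")
            hdr.fileformat = "VCFv4.2"
        if "PASS" not in hdr.filters:
            hdr.filters["PASS"] = FieldDef("PASS", 0, "Flag", "All filters passed")
        return hdr

    def _parse_meta(self, line: str) -> None:
        m = _STRUCTURED_RE.match(line)
        if m and m.group("key") in ("INFO", "FORMAT", "FILTER", "contig"):
            key = m.group("key")
            pairs = dict(_split_structured(m.group("body")))
            fid = pairs.get("ID")
            if fid is None:
                raise FormatError(f"structured header line lacks ID: {line[:60]!r}")
            idx = int(pairs["IDX"]) if "IDX" in pairs else None
            if key == "contig":
                if fid in self.contigs:
                    raise DuplicateIdError(f"duplicate contig declaration {fid}")
                length = pairs.get("length")
                self.contigs[fid] = int(length) if length is not None else None
                self._order.append(("contig", fid))
                if idx is not None:
                    self._explicit_idx[("contig", fid)] = idx
                return
            section = {"INFO": self.infos, "FORMAT": self.formats,
                       "FILTER": self.filters}[key]
            if fid in section:
                raise DuplicateIdError(f"duplicate ##{key} declaration for id {fid}")
            if key == "FILTER":
                fdef = FieldDef(fid, 0, "Flag", _unquote(pairs.get("Description", "")))
            else:
                number = pairs.get("Number", ".")
                fdef = FieldDef(
                    fid,
                    int(number) if number.lstrip("-").isdigit() else number,
                    pairs.get("Type", "String"),
                    _unquote(pairs.get("Description", "")),
                    extra=tuple(
                        (k, v) for k, v in pairs.items()
                        if k not in ("ID", "Number", "Type", "Description", "IDX")
                    ),
                )
            section[fid] = fdef
            self._order.append((key, fid))
            if idx is not None:
                self._explicit_idx[(key, fid)] = idx
            return
        m = _PLAIN_RE.match(line)
        if m and m.group("key") == "fileformat":
            self.fileformat = m.group("value")
            return
        self.extra_lines.append(line)

    def _parse_column_line(self, line: str) -> None:
        cols = line.split("\t")
        if cols[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
            raise FormatError(
                f"malformed #CHROM line: expected fixed columns {_FIXED_COLUMNS}"
            )
        rest = cols[len(_FIXED_COLUMNS):]
        if rest:
            if rest[0] != "FORMAT":
                raise FormatError("#CHROM line has samples but no FORMAT column")
            self.samples = rest[1:]
            if len(set(self.samples)) != len(self.samples):
                raise FormatError("duplicate sample names in #CHROM line")
        else:
            self.samples = []

    # -------------------------------------------------------------- serialize

    def to_lines(self) -> list[str]:
        """Serialize; declaration order is preserved."""
        lines = [f"##fileformat={self.fileformat}"]
        for section, fid in self._order:
            if section == "contig":
                if fid not in self.contigs:
                    continue
                length = self.contigs[fid]
                attrs = f"ID={fid}" + (f",length={length}" if length is not None else "")
                lines.append(f"##contig=<{attrs}>")
                continue
            table = {"INFO": self.infos, "FORMAT": self.formats,
                     "FILTER": self.filters}[section]
            if fid not in table:
                continue
            d = table[fid]
            if section == "FILTER":
                lines.append(f'##FILTER=<ID={d.id},Description="{d.description}">')
            else:
                extra = "".join(f",{k}={v}" for k, v in d.extra)
                lines.append(
                    f"##{section}=<ID={d.id},Number={d.number},Type={d.type},"
                    f'Description="{d.description}"{extra}>'
                )
        lines.extend(self.extra_lines)
        cols = list(_FIXED_COLUMNS)
        if self.samples:
            cols.append("FORMAT")
            cols.extend(self.samples)
        lines.append("\t".join(cols))
        return lines

    def to_text(self) -> str:
        return "\n".join(self.to_lines()) + "\n"

    # --------------------------------------------------------------- mutation

    def _section(self, kind: str) -> dict:
        try:
            return {"info": self.infos, "format": self.formats,
                    "filter": self.filters}[kind]
        except KeyError:
            raise VcfboxError(f"unknown header section {kind!r}") from None

    def add_field(self, kind: str, fdef: FieldDef) -> None:
        """Add an INFO/FORMAT/FILTER declaration; duplicate id is an error."""
        section = self._section(kind)
        if fdef.id in section:
            raise DuplicateIdError(f"{kind} id {fdef.id} already declared")
        section[fdef.id] = fdef
        self._order.append((kind.upper(), fdef.id))

    def remove_field(self, kind: str, fid: str) -> None:
        section = self._section(kind)
        if fid not in section or (kind == "filter" and fid == "PASS"
                                  and ("FILTER", "PASS") not in self._order):
            raise VcfboxError(f"{kind} id {fid} is not declared; cannot remove")
        del section[fid]
        self._order = [o for o in self._order if o != (kind.upper(), fid)]
        if kind == "filter" and fid == "PASS":
            self.filters["PASS"] = FieldDef("PASS", 0, "Flag", "All filters passed")

    def add_contig(self, name: str, length: int | None = None) -> None:
        if name in self.contigs:
            raise DuplicateIdError(f"contig {name} already declared")
        self.contigs[name] = length
        self._order.append(("contig", name))

    def remove_contig(self, name: str) -> None:
        if name not in self.contigs:
            raise VcfboxError(f"contig {name} is not declared; cannot remove")
        del self.contigs[name]
        self._order = [o for o in self._order if o != ("contig", name)]

    def add_sample(self, name: str) -> None:
        if name in self.samples:
            raise DuplicateIdError(f"sample {name} already present")
        self.samples.append(name)

    def remove_sample(self, name: str) -> None:
        try:
            self.samples.remove(name)
        except ValueError:
            raise VcfboxError(f"sample {name} is not present; cannot remove") from None

    def subset_samples(self, names: list[str]) -> "VcfHeader":
        """A copy whose sample axis is exactly ``names`` (validated upstream)."""
        new = VcfHeader(
            fileformat=self.fileformat,
            contigs=dict(self.contigs),
            infos=dict(self.infos),
            formats=dict(self.formats),
            filters=dict(self.filters),
            samples=list(names),
            extra_lines=list(self.extra_lines),
            _order=list(self._order),
            _explicit_idx=dict(self._explicit_idx),
        )
        return new

    # ------------------------------------------------------------- dictionary

    def string_dictionary(self) -> list[str]:
        """The shared FILTER/INFO/FORMAT id dictionary in index order.

        ``PASS`` occupies index 0; remaining ids follow declaration order,
        unless explicit ``IDX=`` attributes (BCF headers) dictate positions.
        An id used in several sections occupies a single slot.
        """
        explicit = {
            k: v for k, v in self._explicit_idx.items() if k[0] != "contig"
        }
        ids_in_order: list[str] = []
        for section, fid in self._order:
            if section == "contig" or fid in ids_in_order:
                continue
            ids_in_order.append(fid)
        if "PASS" not in ids_in_order:
            ids_in_order.insert(0, "PASS")
        if explicit:
            declared = {fid for _, fid in explicit}
            if any(fid not in declared for fid in ids_in_order if fid != "PASS"):
                raise FormatError(
                    "header mixes explicit IDX= attributes with implicit "
                    "dictionary positions"
                )
            size = max(v for v in explicit.values()) + 1
            out: list[str | None] = [None] * max(size, 1)
            for (_, fid), idx in explicit.items():
                if out[idx] not in (None, fid):
                    raise FormatError(f"conflicting IDX={idx} assignments")
                out[idx] = fid
            if out[0] is None:
                out[0] = "PASS"
            return [fid if fid is not None else f"__hole{i}__"
                    for i, fid in enumerate(out)]
        # implicit: PASS first, then declaration order
        out = ["PASS"] + [fid for fid in ids_in_order if fid != "PASS"]
        return out

    def contig_dictionary(self) -> list[str]:
        """Contig dictionary in index order (IDX= honored when present)."""
        explicit = {
            k[1]: v for k, v in self._explicit_idx.items() if k[0] == "contig"
        }
        names = list(self.contigs)
        if explicit:
            if any(n not in explicit for n in names):
                raise FormatError(
                    "header mixes contigs with and without explicit IDX="
                )
            size = max(explicit.values()) + 1
            out: list[str | None] = [None] * size
            for n, idx in explicit.items():
                out[idx] = n
            return [n if n is not None else f"__hole{i}__" for i, n in enumerate(out)]
        return names

    def n_samples(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VcfHeader):
            return NotImplemented
        return (
            self.fileformat == other.fileformat
            and self.contigs == other.contigs
            and self.infos == other.infos
            and self.formats == other.formats
            and {k: v for k, v in self.filters.items()}
            == {k: v for k, v in other.filters.items()}
            and self.samples == other.samples
            and self.extra_lines == other.extra_lines
        )
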