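"""Exception hierarchy.

Every error raised by the library derives from :class:`VcfboxError`, so
callers (and the command-line layer) can distinguish data/format problems
from programming mistakes with a single ``except`` clause.
"""


class VcfboxError(Exception):
    """Base class for all library errors."""


class FormatError(VcfboxError):
    """Malformed input: bad magic bytes, wrong column counts, truncated data."""


class BgzfError(FormatError):
    """The stream is not valid BGZF (missing gzip magic or BC extra field)."""


class PlainGzipError(BgzfError):
    """Gzip data without BGZF block structure; sequential fallback possible."""


class CorruptionError(FormatError):
    """Checksums or declared sizes do not match the data read."""


class SortOrderError(VcfboxError):
    """Records are not coordinate-sorted where sorting is required."""


class DictionaryError(VcfboxError):
    """An INFO/FORMAT/FILTER/contig id is missing from the header dictionary."""


class DuplicateIdError(VcfboxError):
    """A header declaration id collides with an existing one."""


class ValidationError(VcfboxError):
    """A record violates its header declarations (strict mode)."""


class RegionParseError(VcfboxError):
    """A region string does not parse as ``chr``, ``chr:beg`` or ``chr:beg-end``."""


class UnknownSampleError(VcfboxError):
    """A requested sample name is absent from the header."""


class NoGenotypeError(VcfboxError):
    """An operation requiring GT was invoked on data without genotypes."""


class SingleItemError(VcfboxError):
    """More than one FORMAT item was requested for a single table pass."""


class UsageError(VcfboxError):
    """The object was used out of protocol (e.g. write after close)."""
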