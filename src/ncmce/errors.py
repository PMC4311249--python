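"""Exception taxonomy shared across the package.

Data errors (bad input content) derive from :class:`NcmceDataError`; usage
errors (bad arguments / configuration) derive from :class:`NcmceUsageError`.
The CLI maps the former to exit code 1 and the latter to exit code 2.
"""


class NcmceError(Exception):
    """Base class for all package-specific errors."""


class NcmceDataError(NcmceError):
    """The input data is malformed or inconsistent."""


class NcmceUsageError(NcmceError):
    """The caller supplied invalid arguments or configuration."""


class GenotypeParseError(NcmceDataError):
    """A cell could not be parsed as a number (names row/column)."""


class GenotypeStructureError(NcmceDataError):
    """Ragged rows, shape mismatches or other structural problems."""


class IdentityError(NcmceDataError):
    """Duplicate or otherwise invalid sample/SNP identifiers."""


class LabelError(NcmceDataError):
    """Population labels missing or inconsistent with sample ids."""


class VcfFormatError(NcmceDataError):
    """The VCF lacks a GT subfield or is otherwise unusable."""


class EmptyOutputError(NcmceDataError):
    """An operation produced no usable records (e.g. no biallelic sites)."""


class StateError(NcmceUsageError):
    """Operation applied to a matrix in the wrong state (e.g. non-integer)."""


class ImputationError(NcmceDataError):
    """A SNP column cannot be imputed (all values missing)."""


class GroupingError(NcmceDataError):
    """Sample groups are overlapping, empty or otherwise invalid."""


class DimensionError(NcmceUsageError):
    """Requested embedding dimension exceeds what the data supports."""


class DomainError(NcmceUsageError):
    """A numeric argument is outside its valid domain."""


class ConfigError(NcmceUsageError):
    """A generator or run configuration is inconsistent."""
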