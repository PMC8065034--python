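"""Exception hierarchy shared across the package."""


class BespliceError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(BespliceError):
    """Malformed FASTA/GFF3/GTF input."""


class UsageError(BespliceError):
    """Invalid user-supplied configuration (dialect, PAM, window...)."""


class BoundsError(BespliceError):
    """A feature falls outside its contig."""


class ConsistencyError(BespliceError):
    """Objects passed together do not belong together."""


class ConfigError(BespliceError):
    """An editor or fixture configuration is internally invalid."""


class FitError(BespliceError):
    """Too few points (or a bad span) for a local regression."""


class DomainError(BespliceError):
    """A value lies outside the domain an operation is defined on."""


class EmptyInputError(BespliceError):
    """An operation that needs at least one element received none."""
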