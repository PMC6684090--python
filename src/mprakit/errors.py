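"""Exception hierarchy.

All package-specific failures derive from :class:`MPRAError` so callers
(including the CLI, which maps them to exit code 3) can catch one type.
"""


class MPRAError(Exception):
    """Base class for all mprakit errors."""


class InvalidSequenceError(MPRAError):
    """A sequence contains characters outside the expected alphabet."""


class DesignError(MPRAError):
    """The oligo/variant design violates a structural constraint."""


class CapacityError(DesignError):
    """Requested more barcodes than the constrained sequence space holds."""


class SchemaError(MPRAError):
    """A table on disk does not conform to the expected schema."""


class FastqParseError(MPRAError):
    """A FASTQ record could not be parsed; carries the record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class DegenerateSampleError(MPRAError):
    """A sample column is unusable (e.g. zero total counts)."""


class ConfigurationError(MPRAError):
    """The analysis configuration is inconsistent with the data."""


class EstimationError(MPRAError):
    """Empirical prior estimation failed; names the offending parameter."""


class InsufficientDataError(MPRAError):
    """Too few observations to carry out a per-variant test or fit."""


class ConvergenceError(MPRAError):
    """MCMC convergence diagnostics exceeded their threshold."""
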