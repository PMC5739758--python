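"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`CspPocketError`, so callers (and the
command-line driver) can distinguish bad input (exit code 1) from runtime
failures (exit code 2).
"""


class CspPocketError(Exception):
    """Base class for all package errors."""


class ParseError(CspPocketError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(CspPocketError):
    """Parsed data violates a structural invariant (e.g. duplicate records)."""


class InputError(CspPocketError):
    """Arguments are structurally valid but scientifically unusable."""


class InsufficientDataError(InputError):
    """Too few observations to compute the requested statistic."""


class LookupError_(CspPocketError):
    """A requested chain/residue/record does not exist in the input."""


class DegenerateInputError(InputError):
    """Geometry or data is degenerate for the requested operation."""


class FitError(CspPocketError):
    """A model fit failed to converge; carries diagnostics in the message."""


class ConfigError(CspPocketError):
    """A run configuration is missing or inconsistent; names the field."""
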