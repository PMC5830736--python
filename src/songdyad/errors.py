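"""Exception hierarchy shared by all songdyad modules."""


class SongDyadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SongDyadError):
    """A file does not match the documented schema (e.g. a missing column)."""


class ValidationError(SongDyadError, ValueError):
    """Input values violate a documented invariant."""


class ConfigError(SongDyadError):
    """A scenario or study configuration is malformed (e.g. an unknown key)."""


class UndefinedMetricError(SongDyadError):
    """A metric is undefined for this input (e.g. switching rate of a
    single-phrase window, or zero co-sampled grid points).  Callers that
    aggregate over windows catch this and exclude the window."""


class DegenerateTestError(SongDyadError):
    """A statistical test cannot be computed (e.g. zero variance of paired
    differences, or all values tied)."""


class CoverageError(SongDyadError):
    """A track does not cover a requested time, beyond the allowed tolerance."""
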