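"""Exception hierarchy for the ppgnet pipeline.

Every stage raises a subclass of :class:`PPGNetError`, so callers (and the
CLI) can distinguish user/config problems (:class:`ValidationError`) from
runtime failures.
"""


class PPGNetError(Exception):
    """Base class for all ppgnet errors."""


class ValidationError(PPGNetError):
    """Invalid configuration, manifest, or input contract violation."""


class ParseError(ValidationError):
    """A file could not be parsed in the expected dialect."""


class EmptyInputError(ValidationError):
    """An input file or sequence was empty where data is required."""


class DegenerateSegmentError(PPGNetError):
    """A segment is constant (max == min); callers should drop it."""


class GenerationError(PPGNetError):
    """Synthetic-cohort generation could not satisfy its constraints."""


class FilterDesignError(PPGNetError):
    """FIR design request is infeasible (band edges out of range)."""
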