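"""Exception hierarchy.

All errors raised by the package derive from :class:`FatnormsError`, so a
caller can catch everything with one clause; the subclasses also derive from
``ValueError`` to behave conventionally in generic code.
"""


class FatnormsError(Exception):
    """Base class for all package errors."""


class ParameterError(FatnormsError, ValueError):
    """A distribution or simulation parameter is outside its valid range."""


class DegenerateSampleError(FatnormsError, ValueError):
    """A sample is constant (or otherwise degenerate) where variation is required."""


class PrecisionError(FatnormsError, ValueError):
    """The requested estimate cannot be resolved at the given sample size."""
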