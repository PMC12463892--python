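"""Exception hierarchy for ckdsim.

All domain-specific failures derive from :class:`CkdSimError` so callers can
catch the package's errors with one clause; each subclass also derives from
the matching builtin so generic handling keeps working.
"""


class CkdSimError(Exception):
    """Base class for all ckdsim errors."""


class ParameterError(CkdSimError, ValueError):
    """A numeric parameter violates its documented domain."""


class ConfigurationError(CkdSimError, ValueError):
    """A configuration value (strategy name, factor name, config key) is unknown."""


class FormatError(CkdSimError, ValueError):
    """A file's content does not match the expected format."""


class EmptyInputError(CkdSimError, ValueError):
    """An operation received an empty collection or file where data is required."""


class DomainError(CkdSimError, ValueError):
    """A value outside the enumerated domain (e.g. an unknown disease state)."""


class ConsistencyError(CkdSimError, RuntimeError):
    """An internal invariant (e.g. row-stochasticity) failed."""
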