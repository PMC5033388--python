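"""Exception hierarchy.

All user-facing failures derive from :class:`ComplexFoldError` so callers can
catch a single base class; the subclasses distinguish bad inputs, unsupported
requests, and out-of-order API use.
"""


class ComplexFoldError(Exception):
    """Base class for every error raised by this package."""


class ValidationError(ComplexFoldError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(ComplexFoldError, ValueError):
    """An unknown identifier (e.g. parameter-set name) was requested."""


class CapabilityError(ComplexFoldError, RuntimeError):
    """The request is well-formed but outside what the model can evaluate,
    e.g. a non-37 degree temperature against a dG37-only parameter table."""


class StateError(ComplexFoldError, RuntimeError):
    """An operation was invoked before its prerequisites were computed."""


class OverLengthError(ValidationError):
    """The combined strand length exceeds the largest ensemble gate."""
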