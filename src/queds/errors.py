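"""Exception hierarchy shared across the package."""


class QuedsError(Exception):
    """Base class for all package errors."""


class ContextParseError(QuedsError):
    """A serialized clinical context (CSV/JSON) could not be parsed."""


class ValidationError(QuedsError):
    """Input violates a structural invariant (duplicate ids, unknown ids, ...)."""


class StructureSizeError(QuedsError):
    """The delineated state family would exceed the enumeration cap."""


class AdaptiveError(QuedsError):
    """The adaptive session cannot proceed (e.g. no informative item left)."""
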