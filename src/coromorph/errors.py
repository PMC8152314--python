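"""Exception types shared across the package."""


class CoromorphError(ValueError):
    """Base class for domain errors."""


class ValidationError(CoromorphError):
    """A value violates a domain invariant (e.g. inner diameter >= outer)."""


class StructuralError(CoromorphError):
    """The segment graph is not a valid rooted tree (cycle, orphan, multiple roots)."""
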