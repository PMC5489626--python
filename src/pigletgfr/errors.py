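"""Exception hierarchy shared by all pipeline stages."""


class PigletGfrError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PigletGfrError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class ConfigurationError(PigletGfrError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class SchemaError(PigletGfrError, ValueError):
    """A table or profile does not conform to its declared schema."""


class InsufficientDataError(PigletGfrError, ValueError):
    """Too few observations to perform the requested computation."""


class ExtrapolationError(PigletGfrError, ValueError):
    """No valid terminal elimination phase could be identified."""


class ConvergenceError(PigletGfrError, RuntimeError):
    """An iterative procedure failed to reach a fixed point."""
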