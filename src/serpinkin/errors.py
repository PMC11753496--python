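"""Exception hierarchy shared by all analysis modules."""


class SerpinkinError(Exception):
    """Base class for all package errors."""


class FormatError(SerpinkinError):
    """Malformed input file (missing column, too few points, bad record)."""


class UnitError(FormatError):
    """Inconsistent or missing condition-unit declaration."""


class InsufficientDataError(SerpinkinError):
    """Fewer points / groups than the operation requires."""


class DomainError(SerpinkinError):
    """Input values outside the physically meaningful domain."""


class NoTransitionError(SerpinkinError):
    """Melt trace shows no resolvable thermal transition."""


class IncompleteCurveError(SerpinkinError):
    """Kinetic trace has not reached its upper plateau."""


class DegenerateInputError(SerpinkinError):
    """Zero-variance or otherwise degenerate input (e.g. constant B-factors)."""


class EmptyStructureError(SerpinkinError):
    """Coordinate file contains no protein atoms."""


class ConfigError(SerpinkinError):
    """Invalid run configuration (unknown key, unresolvable path)."""
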