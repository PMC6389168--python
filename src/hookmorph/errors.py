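"""Exception hierarchy shared across the package."""


class HookmorphError(Exception):
    """Base class for all package errors."""


class GeometryError(HookmorphError):
    """A geometric construction failed (degenerate hook, missing intersection)."""


class DegenerateInputError(GeometryError):
    """Input without enough geometric information (coincident vertices, ...)."""


class ConstructionError(HookmorphError):
    """Parametric shape parameters produce an invalid (self-intersecting) outline."""


class ParseError(HookmorphError):
    """A landmark or measurement file could not be parsed."""


class AnalysisError(HookmorphError):
    """A statistical routine received data it cannot analyse."""
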