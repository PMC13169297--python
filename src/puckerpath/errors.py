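"""Exception hierarchy."""


class PuckerPathError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(PuckerPathError):
    """Ring geometry is degenerate (coincident/collinear atoms, wrong size)."""


class PlanarRingError(PuckerPathError):
    """Puckering amplitude below the floor: theta/phi are undefined."""


class IntegrationError(PuckerPathError):
    """Langevin integration became unstable (energy overflow)."""


class ConvergenceError(PuckerPathError):
    """An iterative solver did not reach its tolerance."""


class OverlapError(PuckerPathError):
    """Adjacent umbrella windows have no histogram overlap."""


class ParseError(PuckerPathError):
    """A text file did not conform to the expected dialect."""
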