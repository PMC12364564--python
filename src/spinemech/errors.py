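"""Exception hierarchy for spinemech."""


class SpinemechError(Exception):
    """Base class for all spinemech errors."""


class ParameterError(SpinemechError, ValueError):
    """Invalid or inconsistent parameter combination."""


class DegenerateGeometryError(SpinemechError, ValueError):
    """Geometric input too degenerate for the requested operation
    (collinear points, self-intersecting polygon, empty cross-section...)."""


class MeshError(SpinemechError, ValueError):
    """Mesh does not satisfy the preconditions of a mesh operation."""


class TraceFormatError(SpinemechError, ValueError):
    """A force-displacement file could not be parsed into a valid trace."""


class ConvergenceError(SpinemechError, RuntimeError):
    """An iterative algorithm failed to converge within its budget."""
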