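"""Exception hierarchy."""


class IntcoordsError(Exception):
    """Base class for package errors."""


class DegenerateGeometryError(IntcoordsError):
    """A geometry is degenerate for the requested coordinate (zero-length
    difference vector, collinear flanking atoms of a dihedral, ...)."""


class IncompleteSystemError(IntcoordsError):
    """A coordinate system does not span the required 3N-6 (3N-5) space."""


class ConversionGraphError(IntcoordsError):
    """A target coordinate is unreachable through the completion rules."""


class FormatError(IntcoordsError):
    """Malformed input file."""


class ReconstructionError(IntcoordsError):
    """Cartesian reconstruction from internal values failed to converge."""
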