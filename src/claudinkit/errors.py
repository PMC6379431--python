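"""Exception hierarchy shared across the toolkit."""


class ClaudinkitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ClaudinkitError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(ClaudinkitError):
    """A parsed file contained no atoms."""


class LookupError_(ClaudinkitError):
    """A chain or residue requested by name does not exist."""


class EmptySelectionError(ClaudinkitError):
    """An atom selection matched nothing."""


class ValidationError(ClaudinkitError):
    """Invalid parameters or inconsistent inputs."""


class GenerationError(ClaudinkitError):
    """A synthetic-structure generator produced a physically invalid model."""


class InsufficientPointsError(ClaudinkitError):
    """Too few points for a geometric fit."""


class CoverageError(ClaudinkitError):
    """A residue range has too many missing residues for a reliable fit."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class NonConvergenceError(ClaudinkitError):
    """Iterative core selection shrank below its floor.

    Carries the iteration trace as a list of (iteration, core_size, rmsd).
    """

    def __init__(self, message: str, trace=()):
        super().__init__(message)
        self.trace = list(trace)


class DegenerateBundleError(ClaudinkitError):
    """Per-helix axes nearly cancel; no meaningful membrane normal."""


class MissingResidueError(ClaudinkitError):
    """Residues named in a measurement are absent from the model."""


class UnidentifiableCurveError(ClaudinkitError):
    """Binding data do not constrain Kd (no points bracketing half-max)."""


class MappingError(ClaudinkitError):
    """A reference residue cannot be mapped to an alignment column."""
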