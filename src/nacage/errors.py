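"""Exception hierarchy for nacage.

All errors derive from :class:`NacageError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure contracts of the builder, I/O and model layers.
"""


class NacageError(Exception):
    """Base class for all nacage errors."""


class InvalidArgumentError(NacageError, ValueError):
    """An argument violates an operation's precondition."""


class UnsupportedPolyhedronError(NacageError):
    """Requested polyhedron skeleton is not implemented."""


class InfeasibleGeometryError(NacageError):
    """Cage geometry is self-intersecting (inter-edge clearance <= 2 A)."""


class ParseError(NacageError):
    """A structure or mode file could not be parsed."""


class FormatCapacityError(NacageError):
    """Output exceeds a fixed-width format limit (e.g. >99,999 PDB atoms)."""


class EmptySelectionError(NacageError):
    """Node selection produced zero nodes."""


class DuplicateNodeError(NacageError):
    """Two network nodes coincide (zero inter-node distance)."""


class InvalidModeError(InvalidArgumentError):
    """A mode index refers to a zero/rigid-body mode or is out of range."""


class MalformedEnsembleError(NacageError):
    """Multi-model input with inconsistent atom counts across models."""


class IllConditionedFitError(NacageError):
    """Rigid-body superposition is degenerate (e.g. collinear nodes)."""


class InsufficientFramesError(NacageError):
    """Fewer than two frames supplied where an ensemble is required."""


class UndefinedCorrelationError(NacageError):
    """Pearson correlation undefined (a profile is constant)."""


class UnsupportedModeKindError(NacageError):
    """Operation requires directional (ANM/PCA) modes, e.g. NMD export."""


class DisconnectedNetworkWarning(UserWarning):
    """Contact network is disconnected; zero-mode count differs from the
    connected-network expectation. Carries the component count."""

    def __init__(self, message: str, n_components: int):
        super().__init__(message)
        self.n_components = n_components
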