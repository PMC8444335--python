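"""Exception hierarchy for ddembed.

Every rejected input maps to a distinct exception type so the CLI can
translate failures into stable exit codes.
"""


class DDEmbedError(Exception):
    """Base class for all ddembed errors."""


class NormalizationError(DDEmbedError):
    """A direction vector is not normalized to within tolerance."""


class ConfigurationError(DDEmbedError):
    """Invalid run configuration (unsupported grid order, bad epsilon, ...)."""


class InvalidCavityError(DDEmbedError):
    """Cavity parameters are unphysical (non-positive radius, ...)."""


class DegenerateCavityError(InvalidCavityError):
    """Two spheres coincide with identical radii."""


class SingularGeometryError(DDEmbedError):
    """A source coincides with a target of a Coulomb evaluation."""


class FrameDefinitionError(DDEmbedError):
    """A local-frame definition is degenerate or refers to invalid sites."""


class UnsupportedGeometryError(DDEmbedError):
    """An operation requires sources at sphere centers and got something else."""


class IncompleteInputError(DDEmbedError):
    """Required per-node or per-site values are missing."""


class SolverError(DDEmbedError):
    """An iterative solver failed to converge.

    Carries the residual history in ``residuals`` when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class ModelParameterError(DDEmbedError):
    """Unphysical model parameters (e.g. polarizabilities making T non-SPD)."""


class ParseError(DDEmbedError):
    """Malformed input file; message carries the offending line number."""


class StructuralError(DDEmbedError):
    """Dimension mismatch between a state and the system it refers to."""


class GenerationError(DDEmbedError):
    """Synthetic-system generation failed (e.g. packing retries exhausted)."""
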