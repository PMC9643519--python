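"""Exception hierarchy for the ontether package."""


class OntetherError(Exception):
    """Base class for all package errors."""


class MaterialParameterError(OntetherError):
    """Invalid hyperelastic or linear-elastic parameters."""


class InvalidDeformationError(OntetherError):
    """Deformation state with non-positive volume ratio J."""


class MaterialLookupError(OntetherError, KeyError):
    """Requested (region, stiffness level) pair is not in the library."""


class MixtureError(OntetherError):
    """Inconsistent rule-of-mixtures specification."""


class GeometryError(OntetherError):
    """Geometrically impossible configuration."""


class MeshError(OntetherError):
    """Mesh generation or validity failure."""


class ClassificationError(OntetherError):
    """Point cannot be assigned to a tissue region."""


class SolverError(OntetherError):
    """Nonlinear solve failed to converge or produced invalid elements."""

    def __init__(self, message, convergence_log=None):
        super().__init__(message)
        self.convergence_log = convergence_log


class PostprocessError(OntetherError):
    """Invalid post-processing request."""
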