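"""Exception hierarchy shared across the package."""


class FacesymError(Exception):
    """Base class for all package errors."""


class FormatError(FacesymError):
    """A landmark or topology file is structurally malformed."""


class ValidationError(FacesymError):
    """Data is well-formed but violates a model invariant."""


class DegenerateGeometryError(FacesymError):
    """A geometric construction is undefined for the given input
    (coincident irises, zero-norm landmark, collinear point set, ...)."""


class RegistrationError(FacesymError):
    """Registration could not produce a transform."""


class NoConsensusError(RegistrationError):
    """RANSAC failed to find a consensus set of correspondences."""


class NoOverlapError(RegistrationError):
    """ICP found no correspondences within the distance threshold."""
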