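"""Exception taxonomy shared by all jawkit modules."""


class JawkitError(Exception):
    """Base class for all jawkit errors."""


class DegenerateGeometry(JawkitError):
    """Geometric construction is ill-posed (collinear/coincident inputs, vanishing widths)."""


class NearIdentityRotation(JawkitError):
    """Rotation angle below the conditioning floor; screw axis is undefined."""


class MissingLandmark(JawkitError):
    """A required named landmark is absent from the landmark set."""


class AmbiguousSide(JawkitError):
    """Menton lies exactly on the midsagittal plane; deviated side cannot be assigned."""


class InvalidConfig(JawkitError):
    """A generator or pipeline configuration violates its invariants."""


class ProfileGapError(JawkitError):
    """A fossa wall profile does not cover the sector of a joint-space measurement."""


class NoRotationPhase(JawkitError):
    """No initial pure-rotation (terminal hinge) phase found in an open-close recording."""


class DegeneratePath(JawkitError):
    """Path extent too small to define an inclination."""


class PathTooShort(JawkitError):
    """Path shorter than the chord distance required by the measurement."""


class MissingMovement(JawkitError):
    """A required movement recording is absent."""


class SchemaError(JawkitError):
    """An input file violates the documented schema."""


class LengthMismatch(JawkitError):
    """Paired sequences differ in length."""


class DegenerateVariance(JawkitError):
    """Paired differences are constant; the t statistic is undefined."""


class ConstantColumn(JawkitError):
    """A correlation input column is constant."""


class RankDeficient(JawkitError):
    """Correlation matrix is not positive semidefinite within tolerance."""


class NonConvergence(JawkitError):
    """Iterative procedure failed to converge within max_iter."""


class InvalidSpec(JawkitError):
    """A statistical specification (e.g. non-positive effect size) is invalid."""
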