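"""Exception hierarchy for facewatch.

Every error raised on a malformed input or a degenerate geometric
configuration derives from :class:`FacewatchError`, so callers can catch
one base class at pipeline level while tests assert the specific subclass.
"""


class FacewatchError(Exception):
    """Base class for all facewatch errors."""


class StreamFormatError(FacewatchError):
    """A landmark stream line could not be parsed or violates the dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(FacewatchError, ValueError):
    """An input value violates a documented invariant."""


class AbsentFaceError(FacewatchError):
    """A per-face operation was applied to a frame with no face."""


class DegenerateGeometryError(FacewatchError):
    """Aspect-ratio denominators vanish (zero eye or mouth width)."""


class EmptyWindowError(FacewatchError):
    """A window aggregate was requested over zero frames."""


class BehindCameraError(FacewatchError):
    """A model point has non-positive depth in the camera frame."""


class SingularConfigurationError(FacewatchError):
    """PnP correspondences are degenerate (too few / collinear)."""


class ConvergenceError(FacewatchError):
    """Pose refinement failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class ScriptError(FacewatchError, ValueError):
    """A simulator scenario script is invalid (overlaps, bad magnitudes)."""
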