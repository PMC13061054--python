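"""Exception hierarchy shared across the quantification stages."""


class MitophenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MitophenError):
    """An image file could not be interpreted as a calibrated stack."""


class GeometryError(MitophenError):
    """Requested geometry does not fit the image (ROI outside bounds,
    separation exceeding the field of view, overcrowded nucleus field)."""


class DetectionError(MitophenError):
    """A required structure (spindle pole, centrosome, mask) was not found.

    ``frame`` identifies the offending timepoint when applicable.
    """

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        if frame is not None:
            message = f"{message} (frame {frame})"
        super().__init__(message)


class TrackingError(MitophenError):
    """Too many frames of a movie failed detection to report maxima."""


class ProfileError(MitophenError):
    """An intensity profile is too short or degenerate to locate peaks."""


class CalibrationError(MitophenError):
    """Preset calibration failed to converge to its target."""


class NormalizationError(MitophenError):
    """Control-condition normalization is undefined (non-positive mean)."""


class SampleSizeError(MitophenError):
    """Too few observations for a requested statistic."""


class DegenerateVarianceError(MitophenError):
    """All groups have zero within-group variance; ANOVA is undefined."""


class BackgroundError(MitophenError):
    """No pixels remain outside the mask to estimate background from."""


class StageError(MitophenError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
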