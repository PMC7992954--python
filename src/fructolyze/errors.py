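"""Exception hierarchy shared across the pipeline stages."""


class FructolyzeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FructolyzeError):
    """Input table, spec, or config failed a structural check."""


class ParameterError(FructolyzeError):
    """A numeric parameter is outside its admissible range."""


class PlacementError(FructolyzeError):
    """Requested cell density cannot be placed in the field."""


class DegenerateImageError(FructolyzeError):
    """Image has no intensity structure (e.g. constant frame)."""


class InsufficientDataError(FructolyzeError):
    """Too few observations to fit the requested model."""


class NonGlycolyticControlError(FructolyzeError):
    """Glucose arm did not outgrow the no-sugar control; index undefined."""


class FitError(FructolyzeError):
    """Curve fit failed in a way that cannot be reported as unconverged."""


class StageError(FructolyzeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
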