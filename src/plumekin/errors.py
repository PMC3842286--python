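"""Exception hierarchy shared across the pipeline stages."""


class PlumekinError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PlumekinError, ValueError):
    """Invalid configuration (simulation or pipeline)."""


class InputError(PlumekinError, ValueError):
    """Invalid argument to an analysis operation."""


class FitError(PlumekinError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostic context."""


class EmptySeriesError(PlumekinError, RuntimeError):
    """Front-line extraction produced no points.

    Usually means the analysis window excludes every frame or the
    validity/exclusion gates removed all vectors; review the window
    bounds and thresholds.
    """


class StageError(PlumekinError, RuntimeError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
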