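"""Exception hierarchy shared across the package."""


class FlimFretError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FlimFretError, ValueError):
    """Acquisition or run configuration violates an invariant."""


class InvalidModelError(FlimFretError, ValueError):
    """Decay model is structurally invalid (no components, bad lifetimes...)."""


class UnfittableHistogramError(FlimFretError, ValueError):
    """Histogram carries no usable signal (e.g. all-zero counts)."""


class UndefinedBindingError(FlimFretError, ValueError):
    """Binding ratio requested with both donor-species amplitudes zero."""


class DomainError(FlimFretError, ValueError):
    """Scalar input outside the mathematical domain of a metric."""


class FormatError(FlimFretError, ValueError):
    """On-disk table or sidecar metadata violates the documented format."""


class EmptyDatasetError(FormatError):
    """A dataset file exists but contains no rows."""


class ConfigError(FlimFretError, ValueError):
    """Run/design configuration is inconsistent (duplicate names etc.)."""


class PipelineError(FlimFretError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class LowCountWarning(UserWarning):
    """Histogram has fewer photons than recommended for a stable fit."""


class DesignSizeWarning(UserWarning):
    """Condition design yields fewer cells than the study-scale minimum."""
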