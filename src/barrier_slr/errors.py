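"""Exception hierarchy for the pipeline.

Stage failures are raised as subclasses of :class:`BarrierSLRError` so the
CLI and pipeline driver can tag which stage failed.
"""


class BarrierSLRError(Exception):
    """Base class for all package errors."""


class AlignmentError(BarrierSLRError):
    """Raster pair disagrees in shape or georeference."""


class SchemaError(BarrierSLRError):
    """Unknown land-cover code or malformed metadata."""


class ConfigError(BarrierSLRError):
    """Invalid or degenerate configuration."""


class FitError(BarrierSLRError):
    """Model fit failed (singular covariance or non-convergence)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InputError(BarrierSLRError):
    """Empty or unusable model input."""
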