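"""Exception hierarchy shared across the toolkit."""


class OptijError(Exception):
    """Base class for all toolkit errors."""


class GeometryError(OptijError, ValueError):
    """Acquisition geometry inconsistent with the data (counts, shapes, ranges)."""


class FormatError(OptijError, ValueError):
    """A file or array does not have the expected structure."""


class TrackingError(OptijError, RuntimeError):
    """Fiducial tracking failed on too many projections.

    Carries per-angle diagnostics in :attr:`diagnostics` (list of
    ``(index, angle_deg, ok)`` tuples).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class FitError(OptijError, ValueError):
    """Sinusoid fit preconditions violated (too few samples, span too small)."""


class ConfigError(OptijError, ValueError):
    """Run configuration invalid or incomplete."""
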