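"""Exception and warning types shared across the package."""


class SpikeshareError(Exception):
    """Base class for all spikeshare errors."""


class InvalidConfigError(SpikeshareError, ValueError):
    """A configuration value violates its documented constraints."""


class InsufficientDataError(SpikeshareError, ValueError):
    """The input is too short / too small for the requested computation."""


class ValidationError(SpikeshareError, ValueError):
    """An input file or container fails validation."""


class AlignmentError(SpikeshareError, ValueError):
    """Two inputs that must share a frame grid or length do not."""


class EmptyNetworkError(SpikeshareError, ValueError):
    """A network operation received no nodes."""


class AnalysisWarning(UserWarning):
    """Non-fatal analysis condition (degenerate frame, empty state, ...)."""


class DegenerateOutputWarning(AnalysisWarning):
    """The requested configuration can only produce degenerate output."""
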