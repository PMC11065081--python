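"""Exception types shared across the pipeline."""


class PulsevarError(Exception):
    """Base class for all package-specific errors."""


class DegenerateConfigError(PulsevarError):
    """A simulation configuration cannot produce a usable signal."""


class UnsupportedDesignError(PulsevarError):
    """The requested study design is outside what the pipeline supports."""


class InsufficientBeatsError(PulsevarError):
    """Too few beats (or usable beat pairs) for the requested statistic."""


class EmptyDetectionError(PulsevarError):
    """Peak detection returned no peaks under the given parameters."""


class InvalidSeriesError(PulsevarError):
    """An amplitude series violates a precondition (e.g. non-positive mean)."""
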