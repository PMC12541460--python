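class ConfigurationError(ValueError):
    """Invalid kinetic scheme, acquisition, or run configuration."""


class ThresholdFitError(RuntimeError):
    """The two-Gaussian mixture fit did not yield two separable components.

    Raised when the fitted means are closer than half the larger component
    standard deviation; callers should supply a manual threshold instead.
    """
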