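"""Exception hierarchy for holterchaos."""


class HolterChaosError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HolterChaosError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class FormatError(HolterChaosError, ValueError):
    """An input file violates the beat-annotation format contract."""


class InsufficientDataError(HolterChaosError, ValueError):
    """Not enough beats/intervals for the requested computation."""


class DegenerateSeriesError(HolterChaosError, ValueError):
    """The input series has no usable variability (e.g. constant input)."""


class ConfigurationError(HolterChaosError, ValueError):
    """A simulator configuration is internally inconsistent."""


class SaturationError(HolterChaosError, ValueError):
    """Requested ectopy density exceeds what the underlying beats can host."""


class SpectralWindowError(HolterChaosError, ValueError):
    """A window cannot support spectral analysis (gap too long, too short)."""


class ARFitError(HolterChaosError, RuntimeError):
    """Autoregressive model fit is unstable (poles on/outside unit circle)."""


class DesignError(HolterChaosError, ValueError):
    """Degenerate regression design (e.g. all cosinor times equal mod period)."""
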