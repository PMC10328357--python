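"""Exception hierarchy shared across the package."""


class ChartermError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChartermError, ValueError):
    """An input violates a documented precondition."""


class ParseError(ChartermError, ValueError):
    """A spectral file could not be parsed; the message names the location."""


class GridRangeError(ValidationError):
    """A requested wavenumber grid extends beyond the source spectrum span."""


class DegenerateSpectrumError(ValidationError):
    """A spectrum has zero variance and cannot be SNV-normalised."""


class RankDeficiencyError(ValidationError):
    """More latent factors were requested than the data can support."""


class DegenerateDataError(ValidationError):
    """Group data with zero within-group variance (or similar degeneracy)."""


class SpuriousModelError(ChartermError, RuntimeError):
    """A calibration failed permutation validation and refuses to predict."""
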