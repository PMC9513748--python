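"""Exception hierarchy for the sersev pipeline."""


class SersevError(Exception):
    """Base class for all package-specific errors."""


class SpectralFormatError(SersevError):
    """A spectral table is malformed (missing columns, bad values)."""


class GridMismatchError(SersevError):
    """Spectra do not share a single uniform wavenumber grid."""


class DuplicateSpectrumError(SersevError):
    """Duplicate (spectrum_id, wavenumber) rows or duplicate spectrum ids."""


class ExtrapolationError(SersevError):
    """A resampling target lies outside the native wavenumber span."""


class DegenerateSpectrumError(SersevError):
    """A spectrum carries no fingerprint (e.g. constant intensity)."""


class ConfigError(SersevError):
    """Invalid configuration values."""


class ConsistencyError(SersevError):
    """Inputs that must cover or agree with each other do not."""
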