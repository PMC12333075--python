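"""Exception hierarchy shared across the pipeline stages."""


class PeatspecError(Exception):
    """Base class for all package-specific errors."""


class GridError(PeatspecError, ValueError):
    """Wavelength grids are malformed, mismatched, or have empty overlap."""


class MetadataError(PeatspecError, ValueError):
    """Sample metadata is missing, duplicated, or inconsistent with the spectra."""


class ConfigError(PeatspecError, ValueError):
    """A configuration value violates a stage's contract."""


class EmptySpectrumError(PeatspecError, ValueError):
    """An operation would leave a spectrum with no wavelengths."""


class BandError(PeatspecError, ValueError):
    """A sensor band cannot be simulated on the available wavelength grid."""


class GenerationError(PeatspecError, ValueError):
    """Synthetic-data parameters produce physically impossible reflectance."""
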