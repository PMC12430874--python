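"""Exception hierarchy for osiscan."""


class OsiscanError(Exception):
    """Base class for all osiscan errors."""


class ConfigurationError(OsiscanError, ValueError):
    """Invalid configuration (grid, window, ranges, ...)."""


class FormatError(OsiscanError, ValueError):
    """Malformed input file (non-numeric cells, duplicated wavelengths, ...)."""


class SpectrumValidationError(OsiscanError, ValueError):
    """Reflectance values outside the physically plausible range."""


class BandLookupError(OsiscanError, KeyError):
    """Requested wavelength is not on the grid (beyond snap tolerance)."""


class DegenerateInputError(OsiscanError, ValueError):
    """Input too small or too degenerate for the operation (n < 3, zero variance, all scans excluded)."""


class UndefinedCorrelationError(OsiscanError, ValueError):
    """Pearson correlation undefined (constant vector, fewer than 3 defined samples)."""


class ScreeningFailureError(OsiscanError, RuntimeError):
    """Every candidate band combination was undefined."""


class TrainingFailureError(OsiscanError, RuntimeError):
    """Model training diverged or produced non-finite parameters."""
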