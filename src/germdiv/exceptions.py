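"""Named error types raised across the package."""


class GermdivError(Exception):
    """Base class for all package errors."""


class SchemaError(GermdivError):
    """Invalid trait schema."""


class DuplicateAbbreviationError(SchemaError):
    """Two traits share an abbreviation."""


class InvalidClassesError(SchemaError):
    """Qualitative trait with fewer than 2 classes, or classes on a quantitative trait."""


class MatrixError(GermdivError):
    """Invalid phenotype matrix."""


class UnknownColumnError(MatrixError):
    """Input column does not match any schema abbreviation."""


class DuplicateIndividualError(MatrixError):
    """Individual ID occurs more than once."""


class MatrixParseError(MatrixError):
    """A quantitative cell could not be parsed as a finite number."""


class ConfigError(GermdivError):
    """Invalid cohort or run configuration."""


class NotPositiveSemidefiniteError(ConfigError):
    """Correlation matrix is not PSD within tolerance."""


class InsufficientDataError(GermdivError):
    """Too few non-missing observations for the requested statistic."""


class ZeroMeanError(GermdivError):
    """Coefficient of variation undefined: mean is zero."""


class DegenerateGradingError(GermdivError):
    """Ten-level grading undefined: standard deviation is zero."""


class ZeroVarianceError(GermdivError):
    """Operation requires positive variance in every trait."""
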