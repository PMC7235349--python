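"""Exception hierarchy shared across the package."""


class IRSHError(Exception):
    """Base class for all errors raised by irsh."""


class FormatError(IRSHError):
    """A container file is malformed (missing dataset, shape mismatch, ...)."""


class ParseError(IRSHError):
    """A delimited text file could not be parsed; message carries the line number."""


class SpectralRangeError(IRSHError):
    """A wavenumber range selects no channels or extends beyond the data."""


class ConfigurationError(IRSHError):
    """A configuration is self-inconsistent or infeasible."""


class RankError(IRSHError):
    """Requested more components than the data can support."""


class CollinearityError(RankError):
    """An EMSC design matrix is rank deficient; message names the culprit columns."""


class DegeneratePixelError(IRSHError):
    """A fitted multiplicative scale fell below the mask threshold."""


class DataError(IRSHError):
    """Input values are non-finite or otherwise unusable."""


class ConstantSpectrumError(DataError):
    """Correlation is undefined for a constant vector."""
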