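"""Exception hierarchy shared across the pipeline stages."""


class CrmChipError(Exception):
    """Base class for all package-specific errors."""


class PatternError(CrmChipError):
    """An IUPAC motif pattern contains an invalid character."""


class CoordinateError(CrmChipError):
    """A genomic interval falls outside the span it must lie within."""


class ParameterError(CrmChipError):
    """A numeric parameter is outside its documented range."""


class InfeasibleWindowError(CrmChipError):
    """No amplicon window of admissible length fits the sequence."""


class DegenerateInputError(CrmChipError):
    """A mean signal required to be positive is zero or negative."""


class NotDetectedError(CrmChipError):
    """Fewer than two of three qPCR wells amplified ('nd')."""


class ConfigError(CrmChipError):
    """A simulation or pipeline configuration is inconsistent."""
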