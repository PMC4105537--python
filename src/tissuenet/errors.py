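"""Exception hierarchy shared across the pipeline."""


class TissueNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TissueNetError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(TissueNetError):
    """Inputs are structurally inconsistent (cross-file or cross-table)."""


class ParseError(TissueNetError):
    """A file failed to parse; message carries row/column coordinates."""


class ParameterError(TissueNetError):
    """An operation received an out-of-range parameter."""


class DegenerateInputError(TissueNetError):
    """Input has no usable signal (e.g. zero variance everywhere)."""
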