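"""Exception hierarchy for flashox."""


class FlashoxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FlashoxError, ValueError):
    """A model parameter is outside its physical domain."""


class ModelMismatchError(FlashoxError, ValueError):
    """A state or dataset is incompatible with the requested model."""


class NormalizationError(FlashoxError, ValueError):
    """A normalization step is impossible or would be applied twice."""


class ProtocolError(FlashoxError, ValueError):
    """A flash protocol is malformed."""


class DataSchemaError(FlashoxError, ValueError):
    """An input file does not conform to the documented schema."""


class FitError(FlashoxError, RuntimeError):
    """A fit could not be set up or did not produce a usable result."""
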