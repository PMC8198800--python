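"""Exception types shared across the pipeline stages."""


class LnqsprError(Exception):
    """Base class for package errors."""


class InputFormatError(LnqsprError):
    """A file or table does not have the expected structure."""


class EmptyInputError(LnqsprError):
    """An input that must contain data is empty."""


class InvalidSmilesError(LnqsprError):
    """A SMILES string could not be parsed or standardized."""


class ParameterError(LnqsprError):
    """A configuration value is outside its allowed range for the data."""


class TrainingError(LnqsprError):
    """Model optimisation failed (non-finite loss or similar)."""


class CapabilityError(LnqsprError):
    """The requested computation exceeds the configured exact-mode limits."""


class GenerationError(LnqsprError):
    """The scaffold grammar cannot produce the requested library."""
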