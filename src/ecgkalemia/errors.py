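"""Exception hierarchy shared across the package."""


class EcgKalemiaError(Exception):
    """Base class for package errors."""


class ValidationError(EcgKalemiaError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(EcgKalemiaError, ValueError):
    """A file or buffer could not be decoded."""


class RangeError(EcgKalemiaError, ValueError):
    """A sample or parameter is outside its representable range."""


class ConfigurationError(EcgKalemiaError, ValueError):
    """A configuration object is internally inconsistent."""


class DelineationError(EcgKalemiaError, RuntimeError):
    """Beat detection or fiducial localisation failed for a record."""


class TrainingError(EcgKalemiaError, RuntimeError):
    """Model fitting could not proceed (e.g. single-class training data)."""


class SplitError(EcgKalemiaError, ValueError):
    """A requested train/test split cannot be satisfied."""
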