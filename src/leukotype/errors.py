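"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`LeukotypeError`, so callers (and the CLI) can distinguish input
problems from genuine bugs.
"""


class LeukotypeError(Exception):
    """Base class for all errors raised by leukotype."""


class FormatError(LeukotypeError):
    """A file could not be parsed in the declared format."""


class ValidationError(LeukotypeError):
    """Input data violates a documented invariant."""


class DimensionError(ValidationError):
    """A vector or matrix has the wrong shape for the requested operation."""


class VocabularyError(ValidationError):
    """A label falls outside the closed subtype vocabulary."""


class ModelLoadError(LeukotypeError):
    """A persisted model file is unreadable, truncated, or version-mismatched."""


class AmbiguousPeakError(LeukotypeError):
    """Two electropherogram peaks both claim the same amplicon."""


class QuantificationError(LeukotypeError):
    """Standard-curve quantification failed at the sample level."""


class ConfigError(LeukotypeError):
    """A simulation or run configuration is internally inconsistent."""
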