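"""Exception hierarchy for hoverbayes."""


class HoverBayesError(Exception):
    """Base class for all package-specific errors."""


class DegenerateTaskError(HoverBayesError):
    """Raised when a task carries no positive-evidence mass (zero posterior denominator)."""


class InvalidAnswerError(HoverBayesError):
    """Raised for answers that are non-finite or violate numerator <= denominator."""


class SchemaError(HoverBayesError):
    """Raised when tabular input does not match the expected columns or codes."""


class MalformedLogError(HoverBayesError):
    """Raised for hover logs with overlapping or inverted event intervals."""


class UndefinedDwellError(HoverBayesError):
    """Raised when dwell percentages are requested for a zero-duration sequence."""


class NormalizationError(HoverBayesError):
    """Raised when a distribution that must sum to one does not."""


class EmptyGroupError(HoverBayesError):
    """Raised when a group-level operation receives no participants."""


class DegenerateTableError(HoverBayesError):
    """Raised for contingency tables with a zero marginal."""


class ConstantResponseError(HoverBayesError):
    """Raised when a regression response has no variation."""


class ConfigError(HoverBayesError):
    """Raised for invalid simulation or pipeline configuration."""
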