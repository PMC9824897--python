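"""Exception hierarchy."""


class HybridSeekError(Exception):
    """Base class for package errors."""


class ParameterError(HybridSeekError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(HybridSeekError, ValueError):
    """Malformed or unreadable file."""


class EvaluationError(HybridSeekError):
    """A fitness function returned a non-finite value."""


class TrainingError(HybridSeekError, ValueError):
    """Training data cannot support model fitting (e.g. one class only)."""


class UndefinedMetricError(HybridSeekError, ValueError):
    """A metric's denominator is empty (no positives or no negatives)."""
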