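"""Exception hierarchy shared across the package."""


class NephrotextError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NephrotextError, ValueError):
    """A value lies outside its clinically valid domain."""


class ConfigError(NephrotextError, ValueError):
    """Invalid configuration (proportions, fold counts, backend geometry...)."""


class ParseError(NephrotextError, ValueError):
    """Malformed cohort CSV; message names the offending row/column."""


class TemplateError(NephrotextError, ValueError):
    """Prompt template contains unknown or missing placeholders."""


class ShapeError(NephrotextError, ValueError):
    """Array dimensions incompatible with the fusion geometry."""


class TrainingError(NephrotextError, RuntimeError):
    """Optimization diverged (non-finite loss); message carries the epoch."""


class UndefinedMetricError(NephrotextError, ValueError):
    """A metric's denominator is empty (e.g. AUC with a single class)."""
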