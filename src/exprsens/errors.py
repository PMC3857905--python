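"""Exception hierarchy for the expression-sensitivity pipeline.

Every error a caller may want to catch distinctly has its own class; all
inherit from :class:`ExprSensError` so ``except ExprSensError`` catches any
pipeline failure.
"""


class ExprSensError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExprSensError):
    """Invalid configuration value (bad fraction, empty range, bad cutoff)."""


class FormatError(ExprSensError):
    """Malformed input file: ragged rows, non-numeric cells, duplicate IDs."""


class PipelineError(ExprSensError):
    """A stage cannot proceed: no datasets survive a filter, empty universe."""


class StateError(ExprSensError):
    """Operation applied to data in the wrong state (e.g. double log-transform)."""


class NumericError(ExprSensError):
    """A quantity is numerically undefined (e.g. non-positive gene mean in CV)."""


class InputError(ExprSensError):
    """Invalid user-supplied argument (unknown gene, too few samples)."""
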