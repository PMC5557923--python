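"""Exception hierarchy shared across the pipeline.

Validation problems (bad input data, malformed configuration) and numerical
failures (singular fits, degenerate distances) are distinguished so the CLI
can map them to distinct exit codes.
"""


class FuncdispError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FuncdispError, ValueError):
    """Input data or configuration violates a documented invariant."""


class NumericalError(FuncdispError, RuntimeError):
    """A computation is undefined or failed for numerical reasons."""
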