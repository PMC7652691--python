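"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: usage errors -> 1,
DataValidationError -> 2, ComputationError -> 3.
"""


class CoriskError(Exception):
    """Base class for all package errors."""


class DataValidationError(CoriskError, ValueError):
    """Malformed or inconsistent input data (bad cell values, bad config)."""


class ComputationError(CoriskError, RuntimeError):
    """A stage could not produce a result (degenerate table, empty graph...)."""
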