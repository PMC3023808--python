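"""Exception hierarchy.

``InputError`` covers malformed user inputs (bad identifiers, inconsistent
counts), ``ConfigurationError`` covers invalid analysis settings, and
``EstimationError`` covers degenerate statistical situations (for instance a
zero overlap, which makes the overlap estimator infinite).
"""


class PpisizeError(Exception):
    """Base class for all package errors."""


class InputError(PpisizeError, ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(PpisizeError, ValueError):
    """Invalid analysis configuration."""


class EstimationError(PpisizeError, ValueError):
    """Degenerate estimation problem (e.g. empty dataset, zero overlap)."""
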