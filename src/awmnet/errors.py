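"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class AwmnetError(Exception):
    """Base class for all package errors."""


class ConfigError(AwmnetError):
    """Invalid configuration value; message names the offending field."""


class DataError(AwmnetError):
    """Input data violates a precondition (empty result, unmapped feature...)."""


class NumericalError(AwmnetError):
    """A numerical procedure failed (non-convergence, degenerate matrix...)."""
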