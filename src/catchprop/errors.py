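"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems exit
with 2, data problems with 3, and algorithm non-termination with 4.
"""


class CatchpropError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CatchpropError):
    """Invalid or missing configuration: unknown field names, bad enum
    values, out-of-range parameters."""

    exit_code = 2


class DataError(CatchpropError):
    """Invalid input data: duplicate ids, negative demand, points outside
    the tessellation, schema mismatches."""

    exit_code = 3


class NonTerminationError(CatchpropError):
    """Propagation hit the iteration cap with reachable regions still
    unlabelled."""

    exit_code = 4

    def __init__(self, message: str, stuck_regions=()):
        super().__init__(message)
        self.stuck_regions = list(stuck_regions)
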