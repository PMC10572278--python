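"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2,
empty or degenerate data exit 1.
"""


class SharedRiskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SharedRiskError, ValueError):
    """Bad user configuration: missing columns, malformed LD tables, bad paths."""


class EmptyInputError(SharedRiskError, ValueError):
    """An input that must be non-empty is empty (file, join, instrument set)."""


class DegenerateInputError(SharedRiskError, ValueError):
    """Too few instruments for the requested estimator."""


class SimulationError(SharedRiskError, RuntimeError):
    """The simulator could not satisfy its constraints (e.g. unreachable
    selection threshold after bounded rejection sampling)."""
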