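"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/schema problems -> 2,
statistically degenerate inputs -> 3, anything else -> 4.
"""


class HedstratError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HedstratError):
    """A configuration value is missing, malformed, or infeasible."""


class InputError(HedstratError):
    """User-supplied data violates the documented schema or domain."""


class ValidationError(InputError):
    """Data parsed correctly but fails an internal consistency check."""


class DegenerateInputError(HedstratError):
    """Input is structurally valid but the statistic is undefined on it
    (constant covariate, no events, zero callable bases, ...)."""


class FittingError(HedstratError):
    """Iterative model fitting failed to converge or separated."""
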