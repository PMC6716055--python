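"""Exception hierarchy shared across the package."""


class LevyHRVError(Exception):
    """Base class for all package errors."""


class ParameterError(LevyHRVError, ValueError):
    """A parameter is outside its mathematical domain."""


class DataError(LevyHRVError, ValueError):
    """Input data violate a contract (non-positive intervals, malformed file, ...)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested estimate to be meaningful."""


class IntegrationError(LevyHRVError, RuntimeError):
    """A stochastic or quadrature integration failed; the message names the step."""


class ContractError(LevyHRVError, ValueError):
    """A structured input (e.g. a grid density) violates its invariants."""
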