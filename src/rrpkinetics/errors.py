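"""Structured exceptions.

Infeasibility (negative rates, probabilities outside [0, 1], a release rate
below the direct-release floor) is always raised, never silently clamped:
these conditions are the model-falsification levers of the analysis.
"""


class RRPKineticsError(Exception):
    """Base class for all package errors."""


class ProtocolError(RRPKineticsError):
    """Invalid stimulus protocol (non-increasing AP times, bad segment grid)."""


class ParameterError(RRPKineticsError):
    """Invalid model or generator parameter (e.g. p_v outside [0, 1])."""


class TraceError(RRPKineticsError):
    """Trace does not satisfy an operation's precondition."""


class SteadyStateError(RRPKineticsError):
    """A steady state was required but the data do not support one."""


class EstimationError(RRPKineticsError):
    """An estimator could not produce a valid result."""


class InfeasibleModelError(RRPKineticsError):
    """Derived quantity falls outside its physically meaningful range."""
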