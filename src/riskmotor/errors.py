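"""Exception hierarchy for riskmotor.

All errors derive from :class:`RiskmotorError` so callers can catch the
package's failures with a single ``except`` clause; most are also
``ValueError`` subclasses because they signal invalid inputs.
"""


class RiskmotorError(Exception):
    """Base class for all riskmotor errors."""


class InvalidParameterError(RiskmotorError, ValueError):
    """A model or design parameter violates its domain (e.g. sigma_p <= 0)."""


class InconsistentInputError(RiskmotorError, ValueError):
    """Inputs contradict each other (e.g. an observation recorded on a
    no-feedback trial)."""


class RiskBreakdownError(RiskmotorError, ValueError):
    """The exponential-utility integral diverges: 1 + theta*Q*variance <= 0.

    In Whittle's terminology this is the 'neurotic breakdown' of a
    risk-averse decision-maker whose pessimism outweighs any evidence.
    """


class InsufficientDataError(RiskmotorError, ValueError):
    """Too few trials to run the requested analysis."""


class DegenerateDesignError(RiskmotorError, ValueError):
    """The regressor has zero variance; the regression is undefined."""


class UnbalancedDesignError(RiskmotorError, ValueError):
    """The repeated-measures table is incomplete; no imputation is done."""


class IdentifiabilityError(RiskmotorError, ValueError):
    """The data cannot distinguish the requested parameters (e.g. a single
    feedback condition, or no block with a nonzero response cost)."""


class SchemaError(RiskmotorError, ValueError):
    """A trial table or config file does not match the documented schema."""


class ConfigError(RiskmotorError, ValueError):
    """Invalid or unknown configuration keys/values."""


class PipelineError(RiskmotorError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
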