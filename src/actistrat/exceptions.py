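"""Exception hierarchy for the pipeline."""


class ActistratError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ActistratError):
    """An invalid configuration value; the message names the offending field."""


class EmptyInputError(ActistratError):
    """An operation received an empty trip or table."""


class ContractError(ActistratError):
    """A caller violated an operation's precondition (e.g. wrong window length)."""


class StratificationError(ActistratError):
    """A fold scheme cannot be built (e.g. a class with fewer windows than folds)."""


class BandingError(ActistratError):
    """Leave-one-subject-out bands cannot cover every activity."""


class BalancingError(ActistratError):
    """A class-rebalancing method cannot be applied (e.g. an empty class)."""


class UnknownLabelError(ActistratError):
    """A label outside the four-activity alphabet was encountered."""


class LeakageError(ActistratError):
    """Train and test sets intersect; fitting or balancing is refused."""
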