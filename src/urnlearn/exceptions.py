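"""Exception hierarchy for urnlearn."""


class UrnlearnError(Exception):
    """Base class for all urnlearn errors."""


class InvalidDistributionError(UrnlearnError):
    """A probability vector has negative entries or does not sum to one."""


class InvalidProbabilityError(UrnlearnError):
    """A scalar probability lies outside [0, 1]."""


class InsufficientPayoffsError(UrnlearnError):
    """The payoff pool is too small to draw K distinct payoffs."""


class InvalidStateCountError(UrnlearnError):
    """A bin must have at least two states."""


class UnknownPayoffError(UrnlearnError):
    """An observed payoff is absent from the current stage's payoff map."""


class MissingParameterError(UrnlearnError):
    """A model was invoked without all of its required parameters."""


class IncompleteDataError(UrnlearnError):
    """A dataset lacks recorded decisions (or other fields) needed for fitting."""


class InconsistentStateError(UrnlearnError):
    """Two belief states are not adjacent (do not differ by one observation)."""


class FitFailureError(UrnlearnError):
    """The likelihood was non-finite at every restart."""


class ConfigError(UrnlearnError):
    """A run configuration failed validation."""
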