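"""Exception types raised across the SRSA pipeline."""


class SRSAError(Exception):
    """Base class for all srsa errors."""


class UnsupportedStateSpaceError(SRSAError, ValueError):
    """Requested state-space kind is not one of radiating/vertical/horizontal."""


class InvalidCoordinateError(SRSAError, ValueError):
    """A fixation coordinate is NaN or infinite."""


class InconsistentTrialError(SRSAError, ValueError):
    """Fixations from more than one trial were passed where one was expected."""


class EmptyDatasetError(SRSAError, ValueError):
    """An operation that needs at least one record received none."""


class InsufficientDataError(SRSAError, ValueError):
    """Too few trials/participants for the requested statistic."""


class InvalidStateError(SRSAError, ValueError):
    """A state label lies outside the 1..n_states range."""


class DegenerateFitError(SRSAError, ValueError):
    """The regression design is rank-deficient (fewer distinct patterns than components)."""


class UndefinedCorrelationError(SRSAError, ValueError):
    """Pearson correlation requested against a constant matrix."""


class NoCommonSceneError(SRSAError, ValueError):
    """No scene has usable trials in both extreme-score groups."""


class ConfigError(SRSAError, ValueError):
    """Invalid run or cohort configuration."""
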