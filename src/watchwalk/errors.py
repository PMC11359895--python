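"""Exception taxonomy shared across the pipeline."""


class WatchWalkError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(WatchWalkError):
    """Malformed configuration file or invariant violation."""


class DataError(WatchWalkError):
    """Invalid signal data (non-finite samples, missing columns, ...)."""


class ScheduleError(WatchWalkError):
    """Invalid synthetic activity schedule (overlaps, ordering)."""


class FilterError(WatchWalkError):
    """Signal too short (or otherwise unsuitable) for filtering."""


class TrainingError(WatchWalkError):
    """Model training preconditions violated (classes absent, one participant)."""


class CompatibilityError(WatchWalkError):
    """Model/feature version mismatch between artifacts."""


class EstimationError(WatchWalkError):
    """Statistical estimate cannot be formed from the data provided."""
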