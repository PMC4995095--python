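"""Exception hierarchy shared across the pipeline stages."""


class TwitchgateError(Exception):
    """Base class for all package errors."""


class ConfigError(TwitchgateError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ConsistencyError(TwitchgateError, ValueError):
    """Events or intervals violate a structural invariant (ordering, state membership)."""


class ParameterError(TwitchgateError, ValueError):
    """An operation parameter is infeasible for the given data (e.g. filter band vs rate)."""


class EmptyCorrelationError(TwitchgateError, ValueError):
    """No usable trigger had a full perievent window inside the recording."""


class DetectionInfeasibleError(TwitchgateError, RuntimeError):
    """Too few candidate events to derive a detection threshold."""


class UndefinedFrequencyError(TwitchgateError, ValueError):
    """Segment too short for a dominant frequency to be defined."""


class FormatError(TwitchgateError, ValueError):
    """A container file is malformed; the message names the dataset or column."""


class ValidationError(TwitchgateError, ValueError):
    """An event/interval table failed validation on read."""


class DesignError(TwitchgateError, ValueError):
    """The recording cannot accommodate the requested epoch design."""
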