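"""Exception hierarchy shared by all pipeline stages."""


class CasaTrackError(Exception):
    """Base class for all casatrack errors."""


class InvalidInputError(CasaTrackError, ValueError):
    """Input violates a documented precondition."""


class InsufficientLengthError(InvalidInputError):
    """A track is too short for the requested kinematic statistic."""


class ConfigError(CasaTrackError, ValueError):
    """A configuration object is internally inconsistent."""


class UndefinedStatisticError(CasaTrackError, ValueError):
    """A statistic (e.g. the CV with zero overall mean) is undefined."""
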