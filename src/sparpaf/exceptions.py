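"""Exception hierarchy for the sparpaf pipeline."""


class SparpafError(Exception):
    """Base class for all package errors."""


class ParameterError(SparpafError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(SparpafError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class SignalFormatError(SparpafError, ValueError):
    """A signal file could not be parsed."""


class DegenerateSignalError(SparpafError, ValueError):
    """The signal carries no usable amplitude information."""


class InsufficientBeatsError(SparpafError, ValueError):
    """Fewer than two R peaks were found in a segment."""


class StripSelectionError(SparpafError, ValueError):
    """A recording cannot supply the requested sinus-rhythm strips."""


class EmbeddingError(SparpafError, ValueError):
    """The delay embedding is infeasible for the given segment."""


class SrrsError(SparpafError, ValueError):
    """A repeated-random-subsampling request is infeasible."""
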