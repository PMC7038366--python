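"""Exception hierarchy for canegait."""


class CaneGaitError(Exception):
    """Base class for all canegait errors."""


class FormatError(CaneGaitError):
    """A sensor log file does not have the expected layout (header/columns)."""


class DataError(CaneGaitError):
    """Input data violate a precondition (non-monotone time, missing cells, ...)."""


class ParameterError(CaneGaitError):
    """A parameter value is outside its valid range or a constraint is unsatisfiable."""


class SynchronizationError(CaneGaitError):
    """The two sensor streams cannot be aligned (missing landmarks)."""


class FeatureError(CaneGaitError):
    """A stride is unusable for feature extraction."""
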