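"""Exception hierarchy for the cornerflow package."""


class CornerflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CornerflowError, ValueError):
    """A physical or geometric parameter is out of its valid range."""


class InvalidInputError(CornerflowError, ValueError):
    """An input data structure violates a precondition (empty, non-monotone, ...)."""


class InsufficientProfileError(InvalidInputError):
    """A drop profile is too short or degenerate to fit."""


class SegmentationError(CornerflowError):
    """No usable drop silhouette could be segmented from an image."""


class BaselineNotFoundError(CornerflowError):
    """No substrate baseline edge was detected; caller must supply one."""


class NoContactError(CornerflowError):
    """The drop edge does not reach the substrate baseline."""


class InfeasibleDropError(InvalidParameterError):
    """Requested drop parameters produce a closed or detached profile."""


class ConfigurationError(CornerflowError):
    """A pipeline configuration is invalid (bad keys, missing paths, ...)."""
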