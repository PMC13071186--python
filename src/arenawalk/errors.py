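"""Exception hierarchy shared across the package."""


class ArenaWalkError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ArenaWalkError, ValueError):
    """A parameter violates its documented domain."""


class CollinearPointsError(ArenaWalkError, ValueError):
    """Three points supplied for circle fitting are (numerically) collinear."""


class NoInsectError(ArenaWalkError):
    """No foreground object of sufficient area was found in a frame."""


class NoSplitError(ArenaWalkError):
    """Progressive erosion failed to separate the body into two regions."""


class TrackingError(ArenaWalkError):
    """Frame-by-frame labelling failed for an entire recording."""


class NonEstimableError(ArenaWalkError):
    """The dose-response model cannot be estimated from the given counts."""


class StratificationError(ArenaWalkError, ValueError):
    """A class is too small to stratify over the requested folds."""


class ConfigError(ArenaWalkError, ValueError):
    """Pipeline configuration is inconsistent or inputs are missing."""


class StageError(ArenaWalkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
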