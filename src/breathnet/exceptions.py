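"""Exception hierarchy shared across the pipeline stages."""


class BreathnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BreathnetError, ValueError):
    """A configuration value violates a stated invariant."""


class EmptyCohortError(BreathnetError, ValueError):
    """A cohort was requested with zero subjects in both classes."""


class SignalStructureError(BreathnetError, ValueError):
    """A recording lacks the periodic thermal-cycling structure
    required for window extraction (too short, no complete window)."""


class ShapeError(BreathnetError, ValueError):
    """Array dimensions do not match the configured pipeline geometry."""


class TrainingDivergenceError(BreathnetError, RuntimeError):
    """Backpropagation produced non-finite weights or loss."""


class BalancingError(BreathnetError, ValueError):
    """50/50 class balancing is impossible (empty minority class)."""


class FoldConstructionError(BreathnetError, ValueError):
    """A cross-validation training fold would contain a single class."""


class ROCUndefinedError(BreathnetError, ValueError):
    """ROC analysis requested on scores from a single class."""


class DatasetError(BreathnetError, ValueError):
    """A dataset tree or manifest is malformed."""
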