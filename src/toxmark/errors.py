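"""Exception types shared across the package."""


class ToxmarkError(Exception):
    """Base class for package errors."""


class InvalidNameError(ToxmarkError):
    """A chemical name is empty or unusable after canonicalization."""


class DataIntegrityError(ToxmarkError):
    """Input annotations are internally contradictory."""


class ConfigError(ToxmarkError):
    """A configuration object violates its invariants."""


class InsufficientDataError(ToxmarkError):
    """An operation received too few usable values."""


class InfeasiblePlanError(ToxmarkError):
    """A constrained sampling plan could not be completed.

    Carries ``n_placed``, the number of subsets accepted before giving up.
    """

    def __init__(self, message: str, n_placed: int = 0):
        super().__init__(message)
        self.n_placed = n_placed


class StageError(ToxmarkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
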