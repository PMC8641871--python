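"""Exception hierarchy shared across the package."""


class GravidnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GravidnetError):
    """A file does not have the expected columns or encoding."""


class ValidationError(GravidnetError):
    """Data violate a structural invariant (gaps, NaNs, out-of-range values)."""


class DegenerateScaleError(GravidnetError):
    """A weather variable is constant over the training subset (max == min)."""


class InsufficientHistoryError(GravidnetError):
    """A series is shorter than the window length / warm-up it must cover."""


class ArchitectureError(GravidnetError):
    """An architecture specification cannot be realized (e.g. window too short)."""


class DivergenceError(GravidnetError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class PlanError(GravidnetError):
    """An augmentation plan is inconsistent with the available data."""


class DegenerateSeasonError(GravidnetError):
    """Season-length normalizer is non-positive; timing deltas are undefined."""
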