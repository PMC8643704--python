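"""Exception hierarchy shared across the package."""


class HicArchError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(HicArchError, ValueError):
    """Malformed triplet/bins input (non-uniform bins, bad records...)."""


class DegenerateMatrixError(HicArchError, ValueError):
    """A matrix with no usable signal (all bins masked, zero counts)."""


class DimensionError(HicArchError, ValueError):
    """Mismatched bin grids, chromosomes or matrix shapes."""


class WindowError(HicArchError, ValueError):
    """A sliding window that does not fit the matrix."""


class InsufficientDataError(HicArchError, ValueError):
    """Too few valid bins/observations for the requested statistic."""


class UndefinedStrengthError(HicArchError, ValueError):
    """Compartment strength undefined because a pair class is empty."""


class GenerationError(HicArchError, RuntimeError):
    """Synthetic-data generator could not satisfy the requested layout."""


class PipelineError(HicArchError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
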