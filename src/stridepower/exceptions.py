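"""Exception hierarchy for stridepower."""


class StridePowerError(Exception):
    """Base class for all stridepower errors."""


class InvalidInputError(StridePowerError, ValueError):
    """Input data violate a precondition (non-finite, too short, malformed)."""


class WindowSizeError(InvalidInputError):
    """A DFA window size is outside the admissible range."""


class InsufficientScalesError(InvalidInputError):
    """Fewer than two admissible window sizes; the log-log slope is undefined."""


class DegenerateSeriesError(InvalidInputError):
    """Constant (zero-fluctuation) series; DFA alpha is undefined."""


class EmbeddingFailureError(StridePowerError):
    """Circulant embedding produced a materially negative eigenvalue.

    For fractional Gaussian noise with H in (0, 1) the embedding is always
    nonnegative definite, so this signals an implementation bug rather than
    a user error.
    """


class InsufficientDataError(InvalidInputError):
    """A series is too short for the requested windowing."""


class InvalidSampleSizeError(InvalidInputError):
    """Requested resample size exceeds the number of available subjects."""


class PowerNotAchievableError(StridePowerError):
    """No grid point reaches the requested power threshold."""

    def __init__(self, threshold: float, max_power: float):
        self.threshold = threshold
        self.max_power = max_power
        super().__init__(
            f"no grid point reaches power {threshold:.3f}; "
            f"maximum power found was {max_power:.3f}"
        )
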