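"""Exception types shared across the package."""


class PrefCorrError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PrefCorrError, ValueError):
    """A space or run configuration is internally inconsistent."""


class InvalidInputError(PrefCorrError, ValueError):
    """Operation inputs violate a documented precondition."""


class DegenerateDesignError(PrefCorrError, ValueError):
    """Regression design is degenerate (e.g. constant ratings)."""


class BinningError(PrefCorrError, ValueError):
    """A rating bin required by an analysis is empty."""


class ThresholdError(PrefCorrError, ValueError):
    """A selection rule produced an empty set."""


class ZeroNormError(PrefCorrError, ValueError):
    """A direction vector required to be nonzero has zero norm."""


class DimensionMismatchError(PrefCorrError, ValueError):
    """Two objects that must share dimensions do not."""


class TrialParseError(PrefCorrError, ValueError):
    """A trial table row could not be parsed or validated."""
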