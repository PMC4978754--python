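"""Exception and warning types used across the package."""


class APCError(Exception):
    """Base class for all errors raised by apcpolish."""


class BinningError(APCError):
    """Invalid bin arithmetic (mismatched widths, non-contiguous bins)."""


class TableParseError(APCError):
    """A rate/count table file could not be parsed; message carries row/column."""


class TableLayoutError(APCError):
    """Table shapes or bin layouts are inconsistent."""


class CohortLookupError(APCError, KeyError):
    """A requested cohort/age cell lies outside the observed table."""


class NonPositiveRateError(APCError, ValueError):
    """A rate was zero or negative where the analysis requires log rates."""


class ConvergenceWarning(UserWarning):
    """Median polish stopped at max_iter before reaching tolerance."""


class ZeroRateWarning(UserWarning):
    """A derived rate table contains zero cells the analysis will reject."""
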