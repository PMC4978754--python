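"""Five-year age, period, and birth-cohort bins and their Lexis arithmetic.

An age x period table of rates is indexed by closed integer-year bins such
as ages 15-19 and periods 1975-1979.  Each cell belongs to one birth cohort
on the table's diagonal, obtained by subtraction::

    cohort start = period start - age start

so riders aged 15-19 in 1975-1979 were born in 1960-1964.  Bin labels are
formatted with an en dash ("15–19") but both en dash and ASCII hyphen
are accepted on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import BinningError, TableLayoutError

EN_DASH = "–"
_LABEL_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


@dataclass(frozen=True, order=True)
class YearBin:
    """A closed integer range of years, [start, start + width - 1]."""

    start: int
    width: int = 5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise BinningError(f"bin width must be positive, got {self.width}")

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    @property
    def label(self) -> str:
        return f"{self.start}{EN_DASH}{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str) -> "YearBin":
        """Parse a label such as ``"15–19"`` or ``"15-19"``."""
        m = _LABEL_RE.match(label)
        if not m:
            raise BinningError(f"cannot parse bin label {label!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise BinningError(f"bin label {label!r} has end < start")
        return cls(start=start, width=end - start + 1)


class AgeBin(YearBin):
    """A five-year (by default) age group, e.g. 15-19 years."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.start < 0:
            raise BinningError(f"age bin start must be >= 0, got {self.start}")


class PeriodBin(YearBin):
    """A calendar-time window, e.g. 1975-1979."""


class CohortBin(YearBin):
    """A birth-year interval; always derived as period - age, never stored."""


def cohort_of(age: AgeBin, period: PeriodBin) -> CohortBin:
    """Birth cohort occupying the (age, period) cell of a Lexis table.

    Raises
    ------
    BinningError
        If the two bins have different widths (the diagonal is undefined).
    """
    if age.width != period.width:
        raise BinningError(
            f"age width {age.width} != period width {period.width}; "
            "cohort diagonals require equal bin widths"
        )
    return CohortBin(start=period.start - age.start, width=age.width)


def validate_bin_axis(bins: Sequence[YearBin], what: str = "bin") -> None:
    """Check bins are non-empty, equal-width, contiguous, strictly increasing."""
    if not bins:
        raise TableLayoutError(f"{what} axis is empty")
    width = bins[0].width
    for prev, nxt in zip(bins, bins[1:]):
        if nxt.width != width:
            raise TableLayoutError(
                f"{what} bins mix widths {width} and {nxt.width}"
            )
        if nxt.start != prev.start + width:
            raise TableLayoutError(
                f"{what} bins {prev.label} and {nxt.label} are not contiguous"
            )


def parse_axis(labels: Iterable[str], kind: type[YearBin], what: str) -> tuple:
    bins = []
    for pos, lab in enumerate(labels):
        try:
            b = kind.parse(lab)
        except BinningError as exc:
            raise TableParseErrorAt(what, pos, lab) from exc
        bins.append(kind(start=b.start, width=b.width))
    validate_bin_axis(bins, what)
    return tuple(bins)


def TableParseErrorAt(what: str, pos: int, lab: str):
    from .exceptions import TableParseError

    return TableParseError(f"unparseable {what} label {lab!r} at position {pos}")
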