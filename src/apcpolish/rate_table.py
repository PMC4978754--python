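"""Age x period rate and count tables with Lexis-diagonal cohort access.

`RateTable` is the pipeline's universal input: an A x P grid of annualized
mortality rates (deaths per 100,000 person-years) with five-year age bins on
the rows and five-year calendar periods on the columns.  A full table holds
A + P - 1 birth cohorts, each occupying one diagonal; `cohort_series` walks a
cohort's diagonal as it ages through the periods.

`CountTable` carries the raw material (death counts and population
denominators) from which annualized rates are built::

    rate[a, p] = deaths[a, p] / (population[a, p] * period_width) * 100,000
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .bins import AgeBin, CohortBin, PeriodBin, cohort_of, validate_bin_axis
from .exceptions import (
    CohortLookupError,
    NonPositiveRateError,
    TableLayoutError,
    TableParseError,
    ZeroRateWarning,
)

RATE_SCALE = 100_000.0


def _as_bins(values, kind):
    out = []
    for v in values:
        if isinstance(v, kind):
            out.append(v)
        elif isinstance(v, str):
            b = kind.parse(v)
            out.append(kind(start=b.start, width=b.width))
        else:
            out.append(kind(start=int(v)))
    return tuple(out)


@dataclass(frozen=True)
class RateTable:
    """An age x period grid of annualized rates per 100,000 person-years."""

    ages: tuple[AgeBin, ...]
    periods: tuple[PeriodBin, ...]
    rates: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", _as_bins(self.ages, AgeBin))
        object.__setattr__(self, "periods", _as_bins(self.periods, PeriodBin))
        validate_bin_axis(self.ages, "age")
        validate_bin_axis(self.periods, "period")
        if self.ages[0].width != self.periods[0].width:
            raise TableLayoutError("age and period bins must share one width")
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (len(self.ages), len(self.periods)):
            raise TableLayoutError(
                f"rates shape {rates.shape} does not match "
                f"{len(self.ages)} ages x {len(self.periods)} periods"
            )
        if not np.all(np.isfinite(rates)):
            raise TableLayoutError("rates contain non-finite values")
        object.__setattr__(self, "rates", rates)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def width(self) -> int:
        return self.ages[0].width

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    @property
    def cohorts(self) -> tuple[CohortBin, ...]:
        """All A + P - 1 cohorts, ordered oldest (earliest birth) first."""
        oldest = self.periods[0].start - self.ages[-1].start
        return tuple(
            CohortBin(start=oldest + k * self.width, width=self.width)
            for k in range(self.n_cohorts)
        )

    def cohort_at(self, i: int, j: int) -> CohortBin:
        return cohort_of(self.ages[i], self.periods[j])

    def cohort_index(self, cohort: CohortBin | str) -> int:
        """Index of `cohort` among `self.cohorts` (0 = oldest)."""
        cohort = self._coerce_cohort(cohort)
        oldest = self.periods[0].start - self.ages[-1].start
        k, rem = divmod(cohort.start - oldest, self.width)
        if rem or not 0 <= k < self.n_cohorts or cohort.width != self.width:
            valid = ", ".join(c.label for c in self.cohorts)
            raise CohortLookupError(
                f"cohort {cohort.label} is not observed in this table; "
                f"valid cohorts: {valid}"
            )
        return k

    @staticmethod
    def _coerce_cohort(cohort) -> CohortBin:
        if isinstance(cohort, str):
            b = CohortBin.parse(cohort)
            return CohortBin(start=b.start, width=b.width)
        return cohort

    # -- diagonal access ---------------------------------------------------
    def lookup_cohort_rate(self, cohort: CohortBin | str, age: AgeBin | str) -> float:
        """Rate of `cohort` observed at `age` (cell where period = cohort + age)."""
        cohort = self._coerce_cohort(cohort)
        if isinstance(age, str):
            b = AgeBin.parse(age)
            age = AgeBin(start=b.start, width=b.width)
        period_start = cohort.start + age.start
        try:
            i = [a.start for a in self.ages].index(age.start)
        except ValueError:
            raise CohortLookupError(f"age {age.label} not in table") from None
        starts = [p.start for p in self.periods]
        if period_start not in starts:
            missing = PeriodBin(start=period_start, width=self.width)
            raise CohortLookupError(
                f"cohort {cohort.label} at age {age.label} falls in period "
                f"{missing.label}, outside the observed periods "
                f"{self.periods[0].label}..{self.periods[-1].label}"
            )
        return float(self.rates[i, starts.index(period_start)])

    def cohort_series(self, cohort: CohortBin | str) -> list[tuple[AgeBin, float]]:
        """All observed (age, rate) points on a cohort's diagonal, youngest age first."""
        k = self.cohort_index(cohort)
        out = []
        for i in range(self.n_ages):
            j = k - (self.n_ages - 1 - i)
            if 0 <= j < self.n_periods:
                out.append((self.ages[i], float(self.rates[i, j])))
        return out

    def iter_cells(self) -> Iterator[tuple[int, int, AgeBin, PeriodBin, CohortBin, float]]:
        for i, a in enumerate(self.ages):
            for j, p in enumerate(self.periods):
                yield i, j, a, p, self.cohort_at(i, j), float(self.rates[i, j])

    # -- validation front door ----------------------------------------------
    def require_positive(self) -> "RateTable":
        """Raise unless every rate is strictly positive (log-scale entry check)."""
        bad = np.argwhere(self.rates <= 0)
        if bad.size:
            i, j = bad[0]
            raise NonPositiveRateError(
                f"rate {self.rates[i, j]} at cell "
                f"({self.ages[i].label}, {self.periods[j].label}) is not positive; "
                "log-scale analysis requires all rates > 0"
            )
        return self

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rates,
            index=[a.label for a in self.ages],
            columns=[p.label for p in self.periods],
        )

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "age"
        frame.to_csv(path)

    @classmethod
    def read_csv(cls, path, label: str = "all") -> "RateTable":
        return _read_grid_csv(path, cls, label=label)

    def with_label(self, label: str) -> "RateTable":
        return replace(self, label=label)


def _read_grid_csv(path, cls, label: str = "all"):
    """Read a header-row-of-periods, label-column-of-ages CSV grid."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise TableParseError(f"{path}: needs a header row and at least one data row")
    header = rows[0]
    ncol = len(header)
    periods = []
    for j, lab in enumerate(header[1:], start=1):
        try:
            b = PeriodBin.parse(lab)
        except Exception as exc:
            raise TableParseError(
                f"{path}: unparseable period label {lab!r} in header column {j}"
            ) from exc
        periods.append(PeriodBin(start=b.start, width=b.width))
    ages, values = [], []
    for rnum, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise TableParseError(
                f"{path}: row {rnum} has {len(row)} fields, expected {ncol}"
            )
        try:
            b = AgeBin.parse(row[0])
        except Exception as exc:
            raise TableParseError(
                f"{path}: unparseable age label {row[0]!r} at row {rnum}"
            ) from exc
        ages.append(AgeBin(start=b.start, width=b.width))
        vals = []
        for cnum, cell in enumerate(row[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at row {rnum}, column {cnum}"
                ) from exc
        values.append(vals)
    return cls(
        ages=tuple(ages),
        periods=tuple(periods),
        rates=np.array(values, dtype=float),
        label=label,
    )


# backwards-friendly functional aliases
def read_rate_table(path, label: str = "all") -> RateTable:
    """Read a rate table CSV (header of period labels, first column of ages)."""
    return RateTable.read_csv(path, label=label)


def write_rate_table(table: RateTable, path) -> None:
    table.write_csv(path)


@dataclass(frozen=True)
class CountTable:
    """Death counts and population denominators on the same age x period grid."""

    ages: tuple[AgeBin, ...]
    periods: tuple[PeriodBin, ...]
    deaths: np.ndarray
    population: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", _as_bins(self.ages, AgeBin))
        object.__setattr__(self, "periods", _as_bins(self.periods, PeriodBin))
        validate_bin_axis(self.ages, "age")
        validate_bin_axis(self.periods, "period")
        deaths = np.asarray(self.deaths)
        population = np.asarray(self.population, dtype=float)
        shape = (len(self.ages), len(self.periods))
        if deaths.shape != shape or population.shape != shape:
            raise TableLayoutError(
                f"deaths {deaths.shape} / population {population.shape} "
                f"do not match grid {shape}"
            )
        if np.any(deaths < 0):
            raise TableLayoutError("death counts must be non-negative")
        if np.any(population <= 0) or not np.all(np.isfinite(population)):
            raise TableLayoutError("population must be positive and finite")
        object.__setattr__(self, "deaths", deaths.astype(float))
        object.__setattr__(self, "population", population)

    @property
    def width(self) -> int:
        return self.ages[0].width


def build_rate_table(counts: CountTable, scale: float = RATE_SCALE) -> RateTable:
    """Annualized rates per `scale` persons: deaths / (population * bin width).

    Division by the bin width spreads a five-year death count over its five
    person-years so rates are comparable across bin widths.  Zero-death cells
    produce zero rates, which the log-scale analysis front door rejects; a
    warning flags them here.
    """
    rates = counts.deaths / (counts.population * counts.width) * scale
    if np.any(counts.deaths == 0):
        warnings.warn(
            "count table has zero-death cells; the resulting zero rates will "
            "be rejected at analysis entry (rates must be > 0)",
            ZeroRateWarning,
            stacklevel=2,
        )
    return RateTable(
        ages=counts.ages, periods=counts.periods, rates=rates, label=counts.label
    )
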