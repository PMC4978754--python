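"""Tukey median polish of a two-way table of log rates.

Median polish decomposes a matrix into overall + row + column + residual by
iteratively sweeping out row and column medians.  Applied to log rates it
removes additive age (row) and period (column) effects; what survives in the
residuals is, under the multiplicative age-period-cohort model, the cohort
signal carried on the table's diagonals.

The implementation follows standard Tukey accounting: after each row sweep
the median of the accumulated column effects is folded into the overall term
(and symmetrically after each column sweep), keeping the effect vectors
median-centred.  Exact additivity

    overall + row_effects[i] + col_effects[j] + residuals[i, j] == input[i, j]

holds after every sweep, not only at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bins import CohortBin
from .exceptions import ConvergenceWarning, NonPositiveRateError, TableLayoutError
from .rate_table import RateTable


@dataclass(frozen=True)
class PolishDecomposition:
    """Additive decomposition of a two-way table (all terms on the log scale)."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.residuals.shape

    def reconstruct(self) -> np.ndarray:
        """overall + row + column + residual, cell by cell."""
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )

    def to_frame(self, table: RateTable | None = None):
        import pandas as pd

        rows = [a.label for a in table.ages] if table is not None else None
        cols = [p.label for p in table.periods] if table is not None else None
        return pd.DataFrame(self.residuals, index=rows, columns=cols)


def log_transform(table: RateTable) -> np.ndarray:
    """Natural log of every rate; rejects non-positive cells by name."""
    table.require_positive()
    return np.log(table.rates)


def median_polish(
    matrix: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    sweep: str = "rows",
) -> PolishDecomposition:
    """Polish `matrix` until a full row+column sweep moves nothing beyond `tol`.

    Parameters
    ----------
    matrix
        Finite two-way array with at least two rows and two columns.
    tol
        Convergence threshold on the largest absolute median removed in a
        full sweep.
    max_iter
        Maximum number of full sweeps; hitting it sets ``converged=False``
        and emits a :class:`ConvergenceWarning`.
    sweep
        ``"rows"`` (default) subtracts row medians first within each sweep,
        ``"cols"`` subtracts column medians first.  Polish results can differ
        slightly between orders; both are exposed so the sensitivity can be
        measured.
    """
    z = np.asarray(matrix, dtype=float).copy()
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise TableLayoutError(f"median polish needs a 2-D table >= 2x2, got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise TableLayoutError("median polish input contains non-finite values")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if sweep not in ("rows", "cols"):
        raise ValueError("sweep must be 'rows' or 'cols'")

    overall = 0.0
    row_eff = np.zeros(z.shape[0])
    col_eff = np.zeros(z.shape[1])
    converged = False
    iterations = 0

    def _sweep_rows():
        nonlocal overall
        rm = np.median(z, axis=1)
        z[...] -= rm[:, None]
        row_eff[...] += rm
        m = np.median(col_eff)
        col_eff[...] -= m
        overall += m
        return np.abs(rm).max()

    def _sweep_cols():
        nonlocal overall
        cm = np.median(z, axis=0)
        z[...] -= cm[None, :]
        col_eff[...] += cm
        m = np.median(row_eff)
        row_eff[...] -= m
        overall += m
        return np.abs(cm).max()

    for iterations in range(1, max_iter + 1):
        if sweep == "rows":
            moved = max(_sweep_rows(), _sweep_cols())
        else:
            moved = max(_sweep_cols(), _sweep_rows())
        if moved < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"median polish did not converge in {max_iter} sweeps "
            f"(last sweep moved {moved:.3g} > tol {tol:.3g})",
            ConvergenceWarning,
            stacklevel=2,
        )

    return PolishDecomposition(
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=z,
        iterations=iterations,
        converged=converged,
    )


def residuals_by_cohort(
    dec: PolishDecomposition, table: RateTable
) -> list[tuple[CohortBin, float]]:
    """Tag every residual cell with its birth cohort.

    Returns all A x P (cohort, residual) pairs ordered oldest cohort first,
    and within a cohort by increasing age.
    """
    if dec.shape != table.rates.shape:
        raise TableLayoutError(
            f"decomposition shape {dec.shape} does not match table "
            f"{table.rates.shape}"
        )
    pairs: list[tuple[CohortBin, float]] = []
    A, P = dec.shape
    for cohort in table.cohorts:
        k = table.cohort_index(cohort)
        for i in range(A):
            j = k - (A - 1 - i)
            if 0 <= j < P:
                pairs.append((cohort, float(dec.residuals[i, j])))
    return pairs
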