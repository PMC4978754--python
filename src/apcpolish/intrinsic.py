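"""Intrinsic estimator for the age-period-cohort identification problem.

Because cohort = period - age, the effect-coded APC design matrix has a
one-dimensional null space: a linear trend can be shifted freely between
the age, period, and cohort blocks without changing any fitted value.  The
intrinsic estimator resolves this by taking the minimum-norm least-squares
solution — the unique coefficient vector orthogonal to the null direction —
computed here via `numpy.linalg.lstsq` / the Moore-Penrose pseudoinverse.

Coding is sum-to-zero (effect) coding with the last level of each factor as
the implicit negative-sum level, so the intercept is a grand mean and each
reported effect block sums to zero.

The default outcome is least squares on log annualized rates (the scale on
which published tables are reproducible); for `CountTable` inputs a Poisson
log-likelihood variant with log person-year offsets is available via
``fit(method="poisson")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import TableLayoutError
from .polish import log_transform
from .rate_table import CountTable, RateTable, build_rate_table

SV_CUTOFF = 1e-10  # singular values below cutoff * s_max are treated as zero


def _effect_code(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero coding: level l < L-1 -> e_l; level L-1 -> -1 everywhere."""
    M = np.zeros((levels.size, n_levels - 1))
    for r, l in enumerate(levels):
        if l < n_levels - 1:
            M[r, l] = 1.0
        else:
            M[r, :] = -1.0
    return M


@dataclass(frozen=True)
class IEDesign:
    """Effect-coded APC design with its (unit) null-space direction."""

    matrix: np.ndarray          # N x K, N = A*P, K = 1 + (A-1) + (P-1) + (C-1)
    null_vector: np.ndarray     # length K, unit norm
    n_ages: int
    n_periods: int

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def blocks(self) -> dict[str, slice]:
        A, P, C = self.n_ages, self.n_periods, self.n_cohorts
        return {
            "intercept": slice(0, 1),
            "age": slice(1, A),
            "period": slice(A, A + P - 1),
            "cohort": slice(A + P - 1, A + P - 1 + C - 1),
        }


def build_ie_design(table: RateTable) -> IEDesign:
    """One design row per table cell, in row-major (age, period) order."""
    A, P = table.n_ages, table.n_periods
    if A < 2 or P < 2:
        raise TableLayoutError("intrinsic estimator needs at least a 2x2 table")
    age_idx = np.repeat(np.arange(A), P)
    per_idx = np.tile(np.arange(P), A)
    coh_idx = np.array([table.cohort_index(table.cohort_at(i, j))
                        for i in range(A) for j in range(P)])
    C = A + P - 1
    X = np.column_stack(
        [
            np.ones(A * P),
            _effect_code(age_idx, A),
            _effect_code(per_idx, P),
            _effect_code(coh_idx, C),
        ]
    )
    _, s, vt = np.linalg.svd(X, full_matrices=True)
    small = s < SV_CUTOFF * s[0]
    n_null = int(small.sum()) + (vt.shape[0] - s.size)
    if n_null != 1:
        raise TableLayoutError(
            f"expected exactly one null direction in the APC design, found {n_null}"
        )
    null = vt[-1]
    null = null / np.linalg.norm(null)
    return IEDesign(matrix=X, null_vector=null, n_ages=A, n_periods=P)


def analytic_null_vector(n_ages: int, n_periods: int) -> np.ndarray:
    """Closed-form null direction: centred linear trends over the coded blocks.

    Full-length trends alpha_i = i - (A-1)/2, pi_j = -(j - (P-1)/2),
    gamma_k = k - (C-1)/2 cancel exactly on every cell (k = A-1-i+j); in
    coded coordinates the null vector is their first L-1 entries per block,
    with a zero intercept component.  Returned unit-normalized.
    """
    A, P = n_ages, n_periods
    C = A + P - 1
    alpha = np.arange(A) - (A - 1) / 2
    pi = -(np.arange(P) - (P - 1) / 2)
    gamma = np.arange(C) - (C - 1) / 2
    v = np.concatenate([[0.0], alpha[: A - 1], pi[: P - 1], gamma[: C - 1]])
    return v / np.linalg.norm(v)


def _expand_block(coded: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-length sum-to-zero effects and SEs from coded coefficients.

    The implicit last level is -sum(coded); its variance is 1' Cov 1 over
    the block.
    """
    full = np.append(coded, -coded.sum())
    var = np.append(np.diag(cov), cov.sum())
    return full, np.sqrt(np.maximum(var, 0.0))


@dataclass(frozen=True)
class IEDecomposition:
    """Intrinsic-estimator coefficients, all effect blocks summing to zero."""

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    se_intercept: float
    se_age: np.ndarray
    se_period: np.ndarray
    se_cohort: np.ndarray
    coef: np.ndarray            # coded-scale stacked coefficient vector
    fitted: np.ndarray          # length N
    residuals: np.ndarray       # length N
    sigma2: float
    df_resid: float


def fit_intrinsic_estimator(
    design: IEDesign, log_rates: np.ndarray, weights: np.ndarray | None = None
) -> IEDecomposition:
    """Minimum-norm least squares of log rates on the APC design.

    Standard errors use the pseudoinverse-based covariance
    sigma^2 * (X'WX)^+ with the residual variance estimated at
    N - (K - 1) degrees of freedom (one rank deficiency).
    """
    y = np.asarray(log_rates, dtype=float).ravel()
    X = design.matrix
    if y.size != X.shape[0]:
        raise TableLayoutError(
            f"log-rate vector length {y.size} != design rows {X.shape[0]}"
        )
    if not np.all(np.isfinite(y)):
        raise TableLayoutError("log rates contain non-finite values")
    if weights is None:
        Xw, yw = X, y
    else:
        w = np.sqrt(np.asarray(weights, dtype=float).ravel())
        Xw, yw = X * w[:, None], y * w

    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=SV_CUTOFF)
    if rank != design.k - 1:
        raise TableLayoutError(
            f"design rank {rank}, expected {design.k - 1}: rank deficiency "
            "beyond the single APC null direction (multicollinearity)"
        )
    fitted = X @ beta
    resid = y - fitted
    df = X.shape[0] - (design.k - 1)
    if weights is None:
        sigma2 = float(resid @ resid / df)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        sigma2 = float((w * resid**2).sum() / df)
    cov = sigma2 * np.linalg.pinv(Xw.T @ Xw, rcond=SV_CUTOFF)

    blocks = design.blocks()
    age, se_age = _expand_block(beta[blocks["age"]], cov[blocks["age"], blocks["age"]])
    per, se_per = _expand_block(
        beta[blocks["period"]], cov[blocks["period"], blocks["period"]]
    )
    coh, se_coh = _expand_block(
        beta[blocks["cohort"]], cov[blocks["cohort"], blocks["cohort"]]
    )
    return IEDecomposition(
        intercept=float(beta[0]),
        age_effects=age,
        period_effects=per,
        cohort_effects=coh,
        se_intercept=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_age=se_age,
        se_period=se_per,
        se_cohort=se_coh,
        coef=beta,
        fitted=fitted,
        residuals=resid,
        sigma2=sigma2,
        df_resid=float(df),
    )


def _poisson_irls(
    design: IEDesign,
    deaths: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minimum-norm IRLS for Poisson log link: log mu = offset + X beta."""
    X = design.matrix
    y = deaths.ravel().astype(float)
    beta = np.zeros(design.k)
    beta[0] = np.log(max(y.mean(), 1e-12)) - offset.mean()
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / mu
        w = np.sqrt(mu)
        new, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=SV_CUTOFF)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def ie_effect_plot_data(dec: IEDecomposition, table: RateTable, alpha: float = 0.05):
    """Plottable (label, effect, ci_low, ci_high) frames for age, period, cohort."""
    q = stats.norm.ppf(1 - alpha / 2)

    def frame(labels, eff, se):
        return pd.DataFrame(
            {
                "label": labels,
                "effect": eff,
                "ci_low": eff - q * se,
                "ci_high": eff + q * se,
            }
        )

    return {
        "age": frame([a.label for a in table.ages], dec.age_effects, dec.se_age),
        "period": frame(
            [p.label for p in table.periods], dec.period_effects, dec.se_period
        ),
        "cohort": frame(
            [c.label for c in table.cohorts], dec.cohort_effects, dec.se_cohort
        ),
    }


class IntrinsicEstimatorAPC:
    """Intrinsic-estimator APC model over a rate (or count) table."""

    def __init__(self, table: RateTable | CountTable):
        if isinstance(table, CountTable):
            self.counts: CountTable | None = table
            self.table = build_rate_table(table)
        else:
            self.counts = None
            self.table = table
        self.design = build_ie_design(self.table)

    def fit(self, method: str = "ols") -> "IEResults":
        """Fit by least squares on log rates (default) or Poisson counts.

        ``method="poisson"`` requires the model to have been built from a
        `CountTable`; it maximizes the Poisson likelihood of death counts
        with log person-year offsets, still under the minimum-norm
        identification.
        """
        if method == "ols":
            dec = fit_intrinsic_estimator(self.design, log_transform(self.table))
        elif method == "poisson":
            if self.counts is None:
                raise ValueError("poisson fit requires a CountTable input")
            offset = np.log(
                self.counts.population * self.counts.width / 100_000.0
            ).ravel()
            beta = _poisson_irls(self.design, self.counts.deaths, offset)
            # package coefficients with asymptotic (Fisher) covariance
            mu = np.exp(offset + self.design.matrix @ beta)
            Xw = self.design.matrix * np.sqrt(mu)[:, None]
            cov = np.linalg.pinv(Xw.T @ Xw, rcond=SV_CUTOFF)
            blocks = self.design.blocks()
            age, se_age = _expand_block(
                beta[blocks["age"]], cov[blocks["age"], blocks["age"]]
            )
            per, se_per = _expand_block(
                beta[blocks["period"]], cov[blocks["period"], blocks["period"]]
            )
            coh, se_coh = _expand_block(
                beta[blocks["cohort"]], cov[blocks["cohort"], blocks["cohort"]]
            )
            y = self.counts.deaths.ravel()
            dec = IEDecomposition(
                intercept=float(beta[0]),
                age_effects=age, period_effects=per, cohort_effects=coh,
                se_intercept=float(np.sqrt(max(cov[0, 0], 0.0))),
                se_age=se_age, se_period=se_per, se_cohort=se_coh,
                coef=beta,
                fitted=mu,
                residuals=y - mu,
                sigma2=1.0,
                df_resid=float(y.size - (self.design.k - 1)),
            )
        else:
            raise ValueError("method must be 'ols' or 'poisson'")
        return IEResults(model=self, decomposition=dec)


@dataclass(frozen=True)
class IEResults:
    """Fitted intrinsic-estimator decomposition with reporting helpers."""

    model: IntrinsicEstimatorAPC
    decomposition: IEDecomposition

    @property
    def age_effects(self) -> np.ndarray:
        return self.decomposition.age_effects

    @property
    def period_effects(self) -> np.ndarray:
        return self.decomposition.period_effects

    @property
    def cohort_effects(self) -> np.ndarray:
        return self.decomposition.cohort_effects

    def plot_data(self, alpha: float = 0.05):
        return ie_effect_plot_data(self.decomposition, self.model.table, alpha=alpha)

    def cohort_rate_ratios(self, reference) -> pd.Series:
        """exp(cohort effect - reference effect); reference-relative ratios."""
        table = self.model.table
        k = table.cohort_index(table._coerce_cohort(reference))
        rr = np.exp(self.cohort_effects - self.cohort_effects[k])
        return pd.Series(rr, index=[c.label for c in table.cohorts])

    def summary(self) -> str:
        lines = [
            f"Intrinsic-estimator APC fit: table '{self.model.table.label}', "
            f"{self.model.table.n_ages} ages x {self.model.table.n_periods} periods",
            f"intercept {self.decomposition.intercept:.4f} "
            f"(se {self.decomposition.se_intercept:.4f})",
        ]
        for name in ("age", "period", "cohort"):
            frame = self.plot_data()[name]
            lines.append(f"-- {name} effects (sum {frame['effect'].sum():+.2e})")
            for _, row in frame.iterrows():
                lines.append(
                    f"   {row['label']:<12}{row['effect']:+.4f}  "
                    f"[{row['ci_low']:+.4f}, {row['ci_high']:+.4f}]"
                )
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        label = self.model.table.label
        paths = {}
        for name, frame in self.plot_data().items():
            p = outdir / f"ie_{name}_effects_{label}.tsv"
            frame.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths
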