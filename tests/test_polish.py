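import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from apcpolish import (
    ConvergenceWarning,
    NonPositiveRateError,
    log_transform,
    median_polish,
    residuals_by_cohort,
)
from conftest import make_random_table


def oracle_polish(matrix, tol=1e-8, max_iter=100):
    """Deliberately plain re-implementation: alternate row/column median
    subtraction on the raw matrix, no effect bookkeeping, loop until quiet."""
    z = np.array(matrix, dtype=float)
    for _ in range(max_iter):
        moved = 0.0
        for i in range(z.shape[0]):
            m = np.median(z[i])
            z[i] -= m
            moved = max(moved, abs(m))
        for j in range(z.shape[1]):
            m = np.median(z[:, j])
            z[:, j] -= m
            moved = max(moved, abs(m))
        if moved < tol:
            break
    return z


finite_matrices = arrays(
    np.float64,
    shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
)


class TestMedianPolish:
    def test_perfectly_additive_matrix_has_zero_residuals(self, rng):
        r = rng.normal(size=5)
        c = rng.normal(size=4)
        m = r[:, None] + c[None, :]
        dec = median_polish(m)
        assert np.abs(dec.residuals).max() < 1e-8
        np.testing.assert_allclose(dec.reconstruct(), m, atol=1e-10)

    def test_constant_matrix_goes_entirely_to_overall(self):
        dec = median_polish(np.full((3, 4), 2.5))
        assert dec.overall == pytest.approx(2.5)
        assert np.abs(dec.row_effects).max() == 0
        assert np.abs(dec.col_effects).max() == 0
        assert np.abs(dec.residuals).max() == 0

    def test_hand_iterated_corner_example(self):
        # row medians (2,5,8) then column medians (-1,0,1) leave a lone
        # residual of 1 in the bottom-right cell; the next sweep moves nothing.
        m = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 10]], dtype=float)
        dec = median_polish(m)
        expected = np.zeros((3, 3))
        expected[2, 2] = 1.0
        np.testing.assert_allclose(dec.residuals, expected, atol=1e-10)
        assert dec.converged

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(m=finite_matrices)
    def test_additivity_and_idempotence(self, m):
        dec = median_polish(m, max_iter=200)
        np.testing.assert_allclose(dec.reconstruct(), m, atol=1e-9)
        again = median_polish(dec.residuals, max_iter=200)
        assert np.abs(again.residuals - dec.residuals).max() < 1e-6

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(m=finite_matrices)
    def test_transpose_equivariance(self, m):
        a = median_polish(m, sweep="rows", max_iter=200)
        b = median_polish(m.T, sweep="cols", max_iter=200)
        assert a.overall == pytest.approx(b.overall, abs=1e-8)
        np.testing.assert_allclose(a.row_effects, b.col_effects, atol=1e-8)
        np.testing.assert_allclose(a.col_effects, b.row_effects, atol=1e-8)
        np.testing.assert_allclose(a.residuals, b.residuals.T, atol=1e-8)

    def test_agrees_with_independent_sweep_oracle(self, rng):
        for _ in range(20):
            m = rng.normal(size=(4, 5)) * 3
            dec = median_polish(m, max_iter=500)
            np.testing.assert_allclose(
                dec.residuals, oracle_polish(m, max_iter=500), atol=1e-8
            )

    def test_max_iter_reached_warns_and_flags(self):
        # alternating pattern that polishes slowly
        m = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 2.0], [7.0, 2.0, 0.0]])
        with pytest.warns(ConvergenceWarning):
            dec = median_polish(m, tol=1e-12, max_iter=1)
        assert not dec.converged
        assert dec.iterations == 1
        np.testing.assert_allclose(dec.reconstruct(), m, atol=1e-10)

    def test_rejects_non_finite_and_tiny_input(self):
        with pytest.raises(Exception, match="non-finite"):
            median_polish(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(Exception, match="2-D"):
            median_polish(np.array([[1.0, 2.0]]))

    def test_matches_r_stats_medpolish_on_fixture(self, table1, tmp_path):
        """Dual-route check against R's stats::medpolish residuals.

        R stops on a relative change in sum(|residuals|) rather than on the
        size of the last medians swept, so the two fixed points agree only
        to ~1e-3 on this table; the comparison tolerance reflects that
        stopping-rule difference, not numerical error."""
        data = tmp_path / "logrates.csv"
        np.savetxt(data, np.log(table1.rates), delimiter=",")
        script = tmp_path / "mp.R"
        script.write_text(textwrap.dedent(f"""
            x <- as.matrix(read.csv("{data}", header=FALSE))
            mp <- medpolish(x, eps=1e-10, maxiter=200, trace.iter=FALSE)
            write.table(mp$residuals, "{tmp_path}/res.csv",
                        sep=",", row.names=FALSE, col.names=FALSE)
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True)
        r_res = np.loadtxt(tmp_path / "res.csv", delimiter=",")
        ours = median_polish(np.log(table1.rates), tol=1e-10, max_iter=200)
        np.testing.assert_allclose(ours.residuals, r_res, atol=5e-3)


class TestLogTransform:
    def test_unit_rate_maps_to_zero(self):
        t = make_random_table(np.random.default_rng(0))
        t.rates[:] = 1.0
        assert np.abs(log_transform(t)).max() == 0.0

    def test_fixture_cell_log(self, table1):
        assert log_transform(table1)[0, 0] == pytest.approx(np.log(4.63))
        assert log_transform(table1)[0, 0] == pytest.approx(1.5326, abs=1e-4)

    def test_zero_rate_rejected_by_name(self, rng):
        t = make_random_table(rng)
        t.rates[1, 2] = 0.0
        with pytest.raises(NonPositiveRateError, match="20–24.*1985–1989"):
            log_transform(t)


class TestResidualsByCohort:
    def test_fixture_counts(self, table1):
        dec = median_polish(np.log(table1.rates))
        pairs = residuals_by_cohort(dec, table1)
        assert len(pairs) == 112
        counts = {}
        for cohort, _ in pairs:
            counts[cohort.label] = counts.get(cohort.label, 0) + 1
        assert len(counts) == 21
        # extreme diagonals hold exactly one cell each
        assert counts["1895–1899"] == 1 and counts["1995–1999"] == 1
        # the reference cohort has the same depth as the boomer sub-cohorts
        assert counts["1930–1934"] == counts["1955–1959"] == 8

    def test_shape_mismatch_rejected(self, table1, rng):
        other = make_random_table(rng)
        dec = median_polish(np.log(table1.rates))
        with pytest.raises(Exception, match="shape"):
            residuals_by_cohort(dec, other)

    def test_pairs_ordered_oldest_cohort_first(self, table1):
        dec = median_polish(np.log(table1.rates))
        pairs = residuals_by_cohort(dec, table1)
        starts = [c.start for c, _ in pairs]
        assert starts == sorted(starts)
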