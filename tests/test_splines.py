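"""Spline bases against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatlag.splines import (
    SplineSpec,
    eval_natural_cubic,
    eval_quadratic_bspline,
    log_spaced_lag_knots,
    percentile_knots,
)


def cox_de_boor(x: float, i: int, k: int, t: np.ndarray) -> float:
    """Independent textbook recursion for one B-spline basis function."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, i, k - 1, t)
    if t[i + k + 1] > t[i + 1]:
        out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, i + 1, k - 1, t)
    return out


def truncated_power_natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis on all knots (incl. boundary)."""
    xi = np.asarray(knots, dtype=float)
    K = len(xi)

    def d(j):
        return (np.maximum(x - xi[j], 0) ** 3 - np.maximum(x - xi[-1], 0) ** 3) / (xi[-1] - xi[j])

    cols = [np.ones_like(x), x] + [d(j) - d(K - 2) for j in range(K - 2)]
    return np.column_stack(cols)


class TestQuadraticBSpline:
    def test_matches_independent_recursion(self):
        spec = SplineSpec("quadratic_bspline", (24.0,), (12.0, 33.0), intercept=True)
        rng = np.random.default_rng(1)
        pts = rng.uniform(12.01, 32.99, 10)
        got = eval_quadratic_bspline(pts, spec).values
        t = np.array([12.0] * 3 + [24.0] + [33.0] * 3)
        want = np.array([[cox_de_boor(x, i, 2, t) for i in range(4)] for x in pts])
        assert np.abs(got - want).max() < 1e-12

    def test_no_knots_gives_bernstein_polynomials(self):
        spec = SplineSpec("quadratic_bspline", (), (0.0, 1.0), intercept=True)
        x = np.array([0.0, 0.25, 0.5, 0.9, 1.0])
        got = eval_quadratic_bspline(x, spec).values
        want = np.column_stack([(1 - x) ** 2, 2 * x * (1 - x), x**2])
        assert np.abs(got - want).max() < 1e-14

    def test_dropping_intercept_drops_first_column(self):
        full = SplineSpec("quadratic_bspline", (5.0,), (0.0, 10.0), intercept=True)
        part = SplineSpec("quadratic_bspline", (5.0,), (0.0, 10.0), intercept=False)
        x = np.linspace(0, 10, 23)
        assert np.array_equal(
            eval_quadratic_bspline(x, full).values[:, 1:],
            eval_quadratic_bspline(x, part).values,
        )

    @given(
        knot=st.floats(min_value=2.0, max_value=8.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_of_unity(self, knot, seed):
        spec = SplineSpec("quadratic_bspline", (knot,), (0.0, 10.0), intercept=True)
        pts = np.random.default_rng(seed).uniform(0, 10, 1000)
        rowsums = eval_quadratic_bspline(pts, spec).values.sum(axis=1)
        assert np.abs(rowsums - 1.0).max() < 1e-10

    def test_full_column_rank(self):
        spec = SplineSpec("quadratic_bspline", (3.0, 7.0), (0.0, 10.0), intercept=True)
        pts = np.random.default_rng(0).uniform(0, 10, 50)
        vals = eval_quadratic_bspline(pts, spec).values
        assert np.linalg.matrix_rank(vals) == spec.df == 5


class TestNaturalCubic:
    spec = SplineSpec("natural_cubic", (2.5, 6.0), (0.0, 10.0), intercept=True)

    def test_zero_second_derivative_at_boundaries(self):
        # one-sided second difference with Richardson extrapolation; exact for
        # a cubic piece up to roundoff
        h = 1e-3

        def d2(b, sign):
            def stencil(hh):
                pts = np.array([b, b + sign * hh, b + 2 * sign * hh])
                v = eval_natural_cubic(pts, self.spec).values
                return (v[0] - 2 * v[1] + v[2]) / hh**2

            return 2 * stencil(h / 2) - stencil(h)

        assert np.abs(d2(0.0, +1)).max() < 1e-6
        assert np.abs(d2(10.0, -1)).max() < 1e-6

    def test_linear_extrapolation_beyond_boundary(self):
        v = eval_natural_cubic(np.array([10.0, 11.0, 12.0, 13.0]), self.spec).values
        assert np.abs(np.diff(v, n=2, axis=0)).max() < 1e-12
        w = eval_natural_cubic(np.array([-2.0, -1.0, 0.0]), self.spec).values
        assert np.abs(np.diff(w, n=2, axis=0)).max() < 1e-12

    def test_out_of_range_flagged(self):
        b = eval_natural_cubic(np.array([-0.5, 5.0, 10.5]), self.spec)
        assert b.out_of_range.tolist() == [True, False, True]

    def test_fit_matches_truncated_power_oracle(self):
        """Same column space as an independent natural-spline construction."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 200)
        y = np.sin(x) + 0.1 * rng.normal(size=200)
        ours = np.column_stack([np.ones(200), eval_natural_cubic(x, SplineSpec(
            "natural_cubic", (2.5, 6.0), (0.0, 10.0), intercept=False)).values])
        oracle = truncated_power_natural_basis(x, np.array([0.0, 2.5, 6.0, 10.0]))
        fit_ours = ours @ np.linalg.lstsq(ours, y, rcond=None)[0]
        fit_oracle = oracle @ np.linalg.lstsq(oracle, y, rcond=None)[0]
        assert np.abs(fit_ours - fit_oracle).max() < 1e-8

    def test_intercept_prepends_ones(self):
        x = np.linspace(0, 10, 11)
        with_i = eval_natural_cubic(x, self.spec).values
        assert np.array_equal(with_i[:, 0], np.ones(11))
        assert self.spec.df == 4

    def test_full_column_rank(self):
        pts = np.random.default_rng(3).uniform(0, 10, 40)
        vals = eval_natural_cubic(pts, self.spec).values
        assert np.linalg.matrix_rank(vals) == self.spec.df


class TestKnotRules:
    def test_log_spaced_closed_form(self):
        got = log_spaced_lag_knots(10, 2)
        assert np.allclose(got, [10 ** (1 / 3), 10 ** (2 / 3)], atol=1e-12)
        assert np.allclose(log_spaced_lag_knots(10, 1), [np.sqrt(10)], atol=1e-12)

    @given(
        lag_max=st.integers(min_value=2, max_value=40),
        n=st.integers(min_value=1, max_value=6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_log_knots_strictly_inside(self, lag_max, n):
        k = log_spaced_lag_knots(lag_max, n)
        assert np.all(np.diff(k) > 0)
        assert k[0] > 0 and k[-1] < lag_max

    def test_percentile_rule_type7(self):
        assert percentile_knots(np.arange(1, 101), 75) == pytest.approx(75.25)
        assert percentile_knots(np.arange(1, 101), [0, 100]).tolist() == [1, 100]

    def test_percentile_permutation_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        p = rng.permutation(x)
        assert np.array_equal(percentile_knots(x, [25, 50, 90]), percentile_knots(p, [25, 50, 90]))

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            percentile_knots(np.ones(50), [25, 75])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SplineSpec("natural_cubic", (11.0,), (0.0, 10.0))
        with pytest.raises(ValueError):
            SplineSpec("quadratic_bspline", (5.0, 3.0), (0.0, 10.0))
        with pytest.raises(ValueError):
            SplineSpec("cubic", (), (0.0, 1.0))
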