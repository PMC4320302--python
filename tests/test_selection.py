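"""Decay curve, exponential fit, analytic curvature elbow, count selection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from rpmsi.errors import DomainError
from rpmsi.io import InMemoryMSI
from rpmsi.projection import ScoreMatrix, make_basis, project_dataset
from rpmsi.selection import (
    DecayCurve,
    DecayFit,
    curvature,
    decay_curve,
    elbow_reached,
    fit_exponential,
    max_curvature_point,
    normalized_first_sv,
    select_projection_count,
)


def _power_iteration_s1(a: np.ndarray, iters: int = 2000) -> float:
    """Independent largest-singular-value oracle via power iteration on A^T A."""
    g = a.T @ a
    v = np.ones(g.shape[0]) / np.sqrt(g.shape[0])
    for _ in range(iters):
        w = g @ v
        v = w / np.linalg.norm(w)
    return float(np.sqrt(v @ g @ v))


class TestNormalizedFirstSV:
    def test_single_row_is_norm(self):
        row = np.array([[3.0, 4.0]])
        assert normalized_first_sv(row) == pytest.approx(5.0)

    def test_diagonal_matrix(self):
        assert normalized_first_sv(np.diag([3.0, 2.0, 1.0])) == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 50))
        expected = _power_iteration_s1(a) / 20
        assert normalized_first_sv(a) == pytest.approx(expected, rel=1e-8)

    def test_squared_norm_variant(self):
        a = np.diag([4.0, 1.0])
        assert normalized_first_sv(a, norm="s1sq_over_k") == pytest.approx(8.0)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            normalized_first_sv(np.zeros((0, 3)))


class TestDecayCurve:
    def _scores(self, k=30, n=80, seed=0):
        rng = np.random.default_rng(seed)
        return ScoreMatrix(scores=rng.normal(size=(k, n)))

    def test_full_size_single_point(self):
        scores = self._scores()
        curve = decay_curve(scores, [30])
        assert curve.values[0] == pytest.approx(normalized_first_sv(scores.scores))

    def test_subset_size_exceeding_k_rejected(self):
        with pytest.raises(DomainError, match="exceeds"):
            decay_curve(self._scores(), [31])

    def test_prefix_consistency_across_basis_sizes(self, small_phantom):
        dataset, _, _ = small_phantom
        small = project_dataset(dataset, make_basis(10, dataset.n_channels, seed=3))
        large = project_dataset(dataset, make_basis(150, dataset.n_channels, seed=3))
        c_small = decay_curve(small, [5, 10])
        c_large = decay_curve(large, [5, 10])
        np.testing.assert_allclose(c_small.values, c_large.values, rtol=1e-12)

    def test_curve_decreases_on_phantom_scores(self, small_phantom):
        dataset, _, _ = small_phantom
        rhos = []
        for seed in range(10):
            scores = project_dataset(dataset, make_basis(60, dataset.n_channels, seed=seed))
            curve = decay_curve(scores, list(range(2, 61, 4)))
            rhos.append(spearmanr(curve.subset_sizes, curve.values).statistic)
        assert np.mean(rhos) < 0
        assert max(rhos) < 0  # each seed's curve is decreasing overall

    def test_random_policy_deterministic_given_seed(self):
        scores = self._scores()
        c1 = decay_curve(scores, [5, 10, 20], policy="random", seed=4)
        c2 = decay_curve(scores, [5, 10, 20], policy="random", seed=4)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_strictly_increasing_sizes_required(self):
        with pytest.raises(DomainError):
            DecayCurve(subset_sizes=np.array([5, 5]), values=np.array([1.0, 1.0]))


def _curve_from_model(a, b, c, xs, noise_sd=0.0, seed=0):
    xs = np.asarray(xs, dtype=float)
    y = a * np.exp(-b * xs) + c
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(xs))
    return DecayCurve(subset_sizes=xs.astype(int), values=np.clip(y, 0, None))


class TestFitExponential:
    def test_noise_free_recovery(self):
        curve = _curve_from_model(2.0, 0.05, 1.0, np.arange(5, 201, 5))
        fit = fit_exponential(curve)
        assert fit.converged
        assert fit.a == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(0.05, rel=1e-6)
        assert fit.c == pytest.approx(1.0, rel=1e-6)

    def test_constant_curve_degenerate(self):
        curve = DecayCurve(subset_sizes=np.arange(5, 45, 5),
                           values=np.full(8, 3.0))
        fit = fit_exponential(curve)
        assert fit.converged
        assert fit.degenerate or abs(fit.a) < 1e-6

    def test_noisy_b_recovery_within_10_percent(self):
        errs = []
        for seed in range(20):
            curve = _curve_from_model(2.0, 0.05, 1.0, np.arange(5, 201, 5),
                                      noise_sd=0.01, seed=seed)
            fit = fit_exponential(curve)
            assert fit.converged
            errs.append(abs(fit.b - 0.05) / 0.05)
        assert np.median(errs) < 0.10
        assert np.mean(errs) < 0.10

    def test_scale_equivariance(self):
        xs = np.arange(5, 201, 5)
        fit1 = fit_exponential(_curve_from_model(2.0, 0.05, 1.0, xs))
        lam = 7.5
        fit2 = fit_exponential(_curve_from_model(2.0 * lam, 0.05, 1.0 * lam, xs))
        assert fit2.a == pytest.approx(lam * fit1.a, rel=1e-5)
        assert fit2.c == pytest.approx(lam * fit1.c, rel=1e-5)
        assert fit2.b == pytest.approx(fit1.b, rel=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError, match="4"):
            fit_exponential(_curve_from_model(2.0, 0.05, 1.0, [5, 10, 20]))


def _numeric_kappa(fit, x, h=1e-4):
    """Finite-difference curvature oracle."""
    y = fit.predict
    yp = (y(x + h) - y(x - h)) / (2 * h)
    ypp = (y(x + h) - 2 * y(x) + y(x - h)) / h**2
    return abs(ypp) / (1 + yp**2) ** 1.5


class TestCurvature:
    def test_line_has_zero_curvature(self):
        fit = DecayFit(a=0.0, b=1.0, c=5.0, rss=0.0, converged=True)
        assert curvature(fit, 3.0) == 0.0

    def test_closed_form_value_at_origin(self):
        fit = DecayFit(a=1.0, b=1.0, c=0.0, rss=0.0, converged=True)
        assert curvature(fit, 0.0) == pytest.approx(1.0 / 2**1.5)
        assert curvature(fit, 0.0) == pytest.approx(_numeric_kappa(fit, 0.0), rel=1e-5)

    def test_matches_finite_difference(self):
        fit = DecayFit(a=2.5, b=0.07, c=1.3, rss=0.0, converged=True)
        for x in (0.0, 5.0, 30.0, 100.0):
            assert curvature(fit, x) == pytest.approx(_numeric_kappa(fit, x), rel=1e-3)

    def test_invariant_to_vertical_shift(self):
        f1 = DecayFit(a=2.0, b=0.1, c=0.0, rss=0.0, converged=True)
        f2 = DecayFit(a=2.0, b=0.1, c=99.0, rss=0.0, converged=True)
        xs = np.linspace(0, 50, 11)
        np.testing.assert_allclose(curvature(f1, xs), curvature(f2, xs))

    def test_requires_converged_fit(self):
        fit = DecayFit(a=1.0, b=1.0, c=0.0, rss=0.0, converged=False)
        with pytest.raises(DomainError):
            curvature(fit, 1.0)


def _grid_max_kappa(fit, x_hi):
    """Dense-grid + bounded refinement oracle for the curvature maximum."""
    xs = np.linspace(0.0, x_hi, 20001)
    ks = curvature(fit, xs)
    i = int(np.argmax(ks))
    if i == 0:
        return 0.0
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
    res = minimize_scalar(lambda x: -curvature(fit, float(x)),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


class TestMaxCurvaturePoint:
    @pytest.mark.parametrize("a", [0.5, 1.0, 5.0])
    @pytest.mark.parametrize("b", [0.01, 0.1, 1.0])
    def test_closed_form_matches_grid_oracle(self, a, b):
        fit = DecayFit(a=a, b=b, c=0.7, rss=0.0, converged=True)
        x_star = max_curvature_point(fit)
        oracle = _grid_max_kappa(fit, x_hi=max(10.0, 40.0 / b))
        assert x_star == pytest.approx(oracle, abs=1e-6)

    def test_example_unit_parameters(self):
        fit = DecayFit(a=1.0, b=1.0, c=3.0, rss=0.0, converged=True)
        assert max_curvature_point(fit) == pytest.approx(np.log(np.sqrt(2.0)), abs=1e-12)

    def test_boundary_solution_when_ab_small(self):
        fit = DecayFit(a=0.1, b=1.0, c=0.0, rss=0.0, converged=True)
        assert max_curvature_point(fit) == 0.0
        # Grid confirms curvature is monotone decreasing.
        xs = np.linspace(0, 10, 1000)
        ks = curvature(fit, xs)
        assert np.all(np.diff(ks) <= 0)

    def test_independent_of_c(self):
        f1 = DecayFit(a=3.0, b=0.2, c=-4.0, rss=0.0, converged=True)
        f2 = DecayFit(a=3.0, b=0.2, c=40.0, rss=0.0, converged=True)
        assert max_curvature_point(f1) == max_curvature_point(f2)

    def test_degenerate_fit_rejected(self):
        fit = DecayFit(a=-1.0, b=1.0, c=0.0, rss=0.0, converged=True)
        with pytest.raises(DomainError):
            max_curvature_point(fit)


def _grid_root_k_est(fit, fraction):
    """Dense-grid root bracketing oracle for the selection threshold."""
    x_star = max_curvature_point(fit)
    target = fraction * curvature(fit, x_star)
    xs = np.linspace(x_star, x_star + 200.0 / fit.b, 2_000_001)
    ks = curvature(fit, xs)
    below = np.nonzero(ks < target)[0]
    return int(np.ceil(xs[below[0]]))


class TestSelectProjectionCount:
    def test_matches_grid_oracle(self):
        fit = DecayFit(a=1.0, b=1.0, c=0.0, rss=0.0, converged=True)
        assert select_projection_count(fit, 2.0 / 3.0) == _grid_root_k_est(fit, 2.0 / 3.0)

    def test_matches_grid_oracle_paper_scale(self):
        fit = DecayFit(a=40000.0, b=0.09, c=4000.0, rss=0.0, converged=True)
        for fraction in (0.5, 2.0 / 3.0, 0.9):
            assert select_projection_count(fit, fraction) == \
                _grid_root_k_est(fit, fraction)

    def test_always_exceeds_x_star(self):
        for a, b in [(1.0, 1.0), (5.0, 0.1), (100.0, 0.05), (0.5, 0.01)]:
            fit = DecayFit(a=a, b=b, c=0.0, rss=0.0, converged=True)
            try:
                x_star = max_curvature_point(fit)
            except DomainError:
                continue
            assert select_projection_count(fit) > x_star

    def test_fraction_near_one_gives_ceil_of_x_star(self):
        fit = DecayFit(a=1.0, b=1.0, c=0.0, rss=0.0, converged=True)
        x_star = max_curvature_point(fit)
        assert select_projection_count(fit, 0.999999) == int(np.ceil(x_star))

    def test_smaller_fraction_larger_count(self):
        fit = DecayFit(a=5.0, b=0.05, c=1.0, rss=0.0, converged=True)
        counts = [select_projection_count(fit, f) for f in (0.9, 2.0 / 3.0, 0.5)]
        assert counts[0] < counts[1] < counts[2]

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.5, 2.0])
    def test_fraction_bounds(self, fraction):
        fit = DecayFit(a=1.0, b=1.0, c=0.0, rss=0.0, converged=True)
        with pytest.raises(DomainError):
            select_projection_count(fit, fraction)


class TestElbowReached:
    def _fit(self):
        # k_est for this fit is ~120 (paper-like scale).
        return DecayFit(a=2000.0, b=0.04, c=100.0, rss=0.0, converged=True)

    def test_reached_when_curve_extends_past_k_est(self):
        fit = self._fit()
        k_est = select_projection_count(fit)
        assert k_est <= 200
        curve = _curve_from_model(2000.0, 0.04, 100.0, np.arange(5, 201, 5))
        assert elbow_reached(curve, fit) is True

    def test_not_reached_on_truncated_curve(self):
        fit = self._fit()
        curve = _curve_from_model(2000.0, 0.04, 100.0, [2, 4, 6, 8, 10])
        assert elbow_reached(curve, fit) is False

    def test_boundary_is_inclusive(self):
        fit = self._fit()
        k_est = select_projection_count(fit)
        sizes = np.unique(np.append(np.arange(5, k_est, 5), k_est))
        curve = DecayCurve(subset_sizes=sizes,
                           values=fit.predict(sizes.astype(float)))
        assert elbow_reached(curve, fit) is True


def _scores_with_exponential_sv_curve(a, b, c, k, n, seed, noise=5e-3):
    """Score matrix whose normalized-s1 prefix curve follows a*exp(-b*k')+c.

    Rank-1 construction: A = outer(u, v) with ||v|| = 1 and u chosen so that
    ||u[:k']|| = k' * y(k'); the prefix s1 is then exactly k' * y(k').  A
    small seeded perturbation makes each seed's curve distinct.
    """
    ks = np.arange(1, k + 1, dtype=float)
    target = ks * (a * np.exp(-b * ks) + c)      # required ||u[:k']||
    u_sq = np.diff(np.concatenate([[0.0], target**2]))
    assert np.all(u_sq > 0), "k*y(k) must be increasing for this construction"
    u = np.sqrt(u_sq)
    rng = np.random.default_rng(seed)
    v = rng.normal(size=n)
    v /= np.linalg.norm(v)
    A = np.outer(u, v)
    A = A + rng.normal(0.0, noise * np.abs(A).mean(), size=A.shape)
    return ScoreMatrix(scores=A)


def test_end_to_end_k_est_stability_across_seeds():
    """Known-exponential score matrices yield k_est stable (+-10%) over 10 seeds."""
    sizes = list(range(5, 201, 5))
    estimates = []
    for seed in range(10):
        scores = _scores_with_exponential_sv_curve(2.0, 0.05, 1.0, 200, 300, seed)
        fit = fit_exponential(decay_curve(scores, sizes))
        assert fit.converged
        estimates.append(select_projection_count(fit))
    med = np.median(estimates)
    assert np.all(np.abs(np.array(estimates) - med) <= 0.10 * med)
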