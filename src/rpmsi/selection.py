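"""Automatic choice of the number of projections from singular-value decay.

As projections accumulate, the largest singular value of the score matrix,
normalized by the number of projections, decays roughly exponentially and
plateaus once additional projections recover little new variance.  The
workflow is: evaluate the normalized first singular value over nested
subsets of projection rows, fit y(x) = a*exp(-b*x) + c, locate the point of
maximum curvature of the fitted curve analytically, and report the count at
which curvature has fallen to a given fraction (default two-thirds) of its
maximum — at that point the elbow has been passed.

For y = a*exp(-b*x) + c the curvature is

    kappa(x) = |y''| / (1 + y'^2)^(3/2),   y' = -a*b*e^(-bx),  y'' = a*b^2*e^(-bx)

which, writing u = a*b*e^(-bx), is maximized at u = 1/sqrt(2); hence the
interior maximum x* = ln(sqrt(2)*a*b)/b when a*b >= 1/sqrt(2), else the
boundary x* = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from rpmsi.errors import DomainError, NumericalError
from rpmsi.projection import ScoreMatrix

_SQRT2 = float(np.sqrt(2.0))

#: Supported normalizations of the first singular value s1 of the k'-row subset.
SVALUE_NORMS = ("s1_over_k", "s1sq_over_k")


@dataclass(frozen=True)
class DecayCurve:
    """Normalized first-singular-value decay over increasing subset sizes."""

    subset_sizes: np.ndarray
    values: np.ndarray
    subset_policy: str = "prefix"
    svalue_norm: str = "s1_over_k"

    def __post_init__(self):
        sizes = np.asarray(self.subset_sizes, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if len(sizes) != len(vals):
            raise DomainError("subset_sizes and values must align")
        if len(sizes) and np.any(np.diff(sizes) <= 0):
            raise DomainError("subset_sizes must be strictly increasing")
        if np.any(vals < 0):
            raise DomainError("curve values must be non-negative")
        object.__setattr__(self, "subset_sizes", sizes)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class DecayFit:
    """Fitted three-parameter exponential y = a*exp(-b*x) + c."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=np.float64)
        return self.a * np.exp(-self.b * x) + self.c


def normalized_first_sv(scores: ScoreMatrix | np.ndarray,
                        norm: str = "s1_over_k") -> float:
    """Largest singular value of the score (sub)matrix, normalized by its row count.

    ``s1_over_k`` returns s1/k'; ``s1sq_over_k`` returns s1^2/k'.
    """
    a = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise DomainError("score matrix must be non-empty and 2-D")
    if norm not in SVALUE_NORMS:
        raise DomainError(f"unknown svalue norm {norm!r}; expected one of {SVALUE_NORMS}")
    s1 = float(np.linalg.svd(a, compute_uv=False)[0])
    kp = a.shape[0]
    return s1 / kp if norm == "s1_over_k" else s1 * s1 / kp


def decay_curve(scores: ScoreMatrix, subset_sizes, policy: str = "prefix",
                norm: str = "s1_over_k", seed: int = 0,
                n_draws: int = 5) -> DecayCurve:
    """Evaluate the normalized first singular value over row subsets.

    ``prefix`` (default) uses the first k' rows in basis order, which makes
    the curve deterministic for one basis and consistent under basis
    extension.  ``random`` averages over ``n_draws`` seeded random subsets
    per size.
    """
    sizes = np.asarray(subset_sizes, dtype=np.int64)
    if len(sizes) == 0:
        raise DomainError("subset_sizes must be non-empty")
    if np.any(sizes < 1):
        raise DomainError("subset sizes must be >= 1")
    if sizes.max() > scores.k:
        raise DomainError(
            f"subset size {int(sizes.max())} exceeds available projections k={scores.k}")
    if policy not in ("prefix", "random"):
        raise DomainError(f"unknown subset policy {policy!r}")

    values = np.empty(len(sizes), dtype=np.float64)
    if policy == "prefix":
        for i, kp in enumerate(sizes):
            values[i] = normalized_first_sv(scores.scores[:kp], norm=norm)
    else:
        rng = np.random.default_rng(seed)
        for i, kp in enumerate(sizes):
            draws = [normalized_first_sv(
                scores.scores[rng.choice(scores.k, size=kp, replace=False)], norm=norm)
                for _ in range(n_draws)]
            values[i] = float(np.mean(draws))
    return DecayCurve(subset_sizes=sizes, values=values, subset_policy=policy,
                      svalue_norm=norm)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-linear initialization: fit log(y - min(y)) against x."""
    c0 = float(y.min())
    z = y - c0
    mask = z > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(x[mask], np.log(z[mask]), 1)
        b0 = -float(slope)
        a0 = float(np.exp(intercept))
        if b0 > 0 and np.isfinite(a0):
            return a0, b0, c0
    # Fallback for flat or non-decreasing curves.
    span = float(x.max() - x.min()) or 1.0
    return float(y[0] - y[-1]) or 1e-8, 1.0 / span, float(y[-1])


def fit_exponential(curve: DecayCurve) -> DecayFit:
    """Least-squares fit of y = a*exp(-b*x) + c to the decay curve.

    Deterministic: initialized from a log-linear fit of the min-shifted
    values.  Non-convergence is reported via ``converged=False`` rather than
    raising; a near-constant curve yields a fit flagged ``degenerate``.
    """
    x = curve.subset_sizes.astype(np.float64)
    y = curve.values
    if len(np.unique(x)) < 4:
        raise DomainError("fit requires at least 4 distinct subset sizes")

    a0, b0, c0 = _initial_guess(x, y)

    def model(xv, a, b, c):
        return a * np.exp(-b * xv) + c

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=(a0, b0, c0),
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        a, b, c = (float(v) for v in popt)
        converged = all(np.isfinite(v) for v in (a, b, c))
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        a, b, c, converged = a0, b0, c0, False

    rss = float(np.sum((model(x, a, b, c) - y) ** 2))
    scale = max(float(np.max(np.abs(y))), 1e-300)
    degenerate = abs(a) < 1e-8 * scale or (float(np.ptp(y)) < 1e-12 * scale)
    return DecayFit(a=a, b=b, c=c, rss=rss, converged=converged, degenerate=degenerate)


def curvature(fit: DecayFit, x) -> np.ndarray | float:
    """Curvature kappa(x) = |y''| / (1 + y'^2)^(3/2) of the fitted curve."""
    if not fit.converged:
        raise DomainError("curvature requires a converged fit")
    x = np.asarray(x, dtype=np.float64)
    e = np.exp(-fit.b * x)
    yp = -fit.a * fit.b * e
    ypp = fit.a * fit.b * fit.b * e
    kappa = np.abs(ypp) / (1.0 + yp * yp) ** 1.5
    return float(kappa) if kappa.ndim == 0 else kappa


def max_curvature_point(fit: DecayFit) -> float:
    """Location x* >= 0 of maximum curvature, in closed form.

    Interior solution x* = ln(sqrt(2)*a*b)/b when a*b >= 1/sqrt(2); otherwise
    curvature is maximal at the boundary x* = 0.
    """
    if not fit.converged:
        raise DomainError("max_curvature_point requires a converged fit")
    if fit.a <= 0 or fit.b <= 0 or fit.degenerate:
        raise DomainError(
            f"degenerate fit (a={fit.a:.3g}, b={fit.b:.3g}): no curvature maximum")
    ab = fit.a * fit.b
    if ab < 1.0 / _SQRT2:
        return 0.0
    return float(np.log(_SQRT2 * ab) / fit.b)


def select_projection_count(fit: DecayFit, fraction: float = 2.0 / 3.0) -> int:
    """Smallest integer count past the elbow.

    Finds the first x > x* where curvature has dropped to ``fraction`` of its
    maximum (bracketed root-finding on the strictly decreasing branch) and
    rounds up; the result always exceeds x*.
    """
    if not (0.0 < fraction < 1.0):
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    x_star = max_curvature_point(fit)  # validates the fit
    kappa_star = curvature(fit, x_star)
    if kappa_star <= 0:
        raise DomainError("zero curvature at the maximum: cannot select a count")
    target = fraction * kappa_star

    lo = x_star
    width = 20.0 / fit.b
    hi = lo + width
    for _ in range(200):
        if curvature(fit, hi) < target:
            break
        width *= 2.0
        hi = lo + width
    else:
        raise NumericalError("could not bracket the curvature threshold")

    root = optimize.brentq(lambda x: curvature(fit, x) - target, lo, hi,
                           xtol=1e-10, maxiter=200)
    k_est = int(np.ceil(root))
    if k_est <= x_star:
        k_est = int(np.floor(x_star)) + 1
    return max(k_est, 1)


def elbow_reached(curve: DecayCurve, fit: DecayFit,
                  fraction: float = 2.0 / 3.0) -> bool:
    """True iff the selected count lies within the measured curve range."""
    return select_projection_count(fit, fraction) <= int(curve.subset_sizes.max())
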