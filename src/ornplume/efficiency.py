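"""Coding-accuracy (Fisher information) profiles and efficient-coding
comparisons.

The Fisher information of the duration-rate encoding model,
``F(s) = gamma'(s)^2 / sigma^2(s)``, bounds from below the precision with
which an ideal observer can decode the log blank duration ``s`` from the
spike count.  Efficient coding predicts three relationships between ``F``
and the stimulus-timescale density ``f(s)`` (log blank durations): the
modes of F and f align; the stimulus-weighted average ``<F>`` is maximal
for the matching plume statistics; and the Jeffreys prior ``p_J ∝ sqrt(F)``
reproduces ``f`` (mutual-information optimality under many-sensor pooling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import pearsonr

from .encoding import DurationRateFit
from .plume import TimescaleBounds, blank_dist, log_blank_cdf, log_blank_density

__all__ = [
    "FisherProfile",
    "JeffreysPrior",
    "QQResult",
    "AvgFisherComparison",
    "fisher_profile",
    "profile_from_function",
    "normalize_profile",
    "average_fisher",
    "matched_vs_mismatched",
    "median_log_blank",
    "jeffreys_prior",
    "qq_compare",
    "mode_correlation",
    "reparameterize",
]


@dataclass
class FisherProfile:
    """Fisher information on a grid of log10 blank durations."""

    grid: np.ndarray
    F: np.ndarray
    mode: float
    support: tuple[float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.grid.shape != self.F.shape:
            raise ValueError("grid and F must have the same shape")
        if np.any(self.F < 0):
            raise ValueError("Fisher information must be non-negative")
        if not self.support[0] <= self.mode <= self.support[1]:
            raise ValueError("mode must lie within the support")

    def interp(self, s) -> np.ndarray:
        """Linear interpolation of F at query points (clamped at the edges)."""
        return np.interp(np.asarray(s, dtype=float), self.grid, self.F)


def fisher_profile(fit: DurationRateFit) -> FisherProfile:
    """Fisher approximation ``F(s) = gamma'(s)^2 / sigma^2(s)`` on the fit grid.

    The mode is the grid argmax (smallest index on ties).  Values in the
    outer 20% of the support should be treated as unreliable (few samples,
    influential outliers); comparisons downstream use the central region.
    """
    grid = fit.grid
    gprime = np.asarray(fit.gamma_prime(grid), dtype=float)
    var = np.asarray(fit.sigma2(grid), dtype=float)
    if np.any(var <= 0):
        raise ValueError("sigma^2 must be strictly positive on the grid")
    F = gprime**2 / var
    mode = float(grid[int(np.argmax(F))])
    return FisherProfile(grid=grid, F=F, mode=mode, support=fit.support)


def profile_from_function(
    func: Callable, support: tuple[float, float], grid_size: int = 201
) -> FisherProfile:
    """Build a profile by evaluating a Fisher-information function on a grid."""
    grid = np.linspace(support[0], support[1], grid_size)
    F = np.asarray(func(grid), dtype=float)
    if F.shape != grid.shape:
        F = np.full_like(grid, float(func(grid[0])))
    mode = float(grid[int(np.argmax(F))])
    return FisherProfile(grid=grid, F=F, mode=mode, support=support)


def normalize_profile(profile: FisherProfile) -> FisherProfile:
    """Scale the profile so its maximum is 1 (mode unchanged)."""
    peak = float(profile.F.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero Fisher profile")
    return FisherProfile(
        grid=profile.grid.copy(),
        F=profile.F / peak,
        mode=profile.mode,
        support=profile.support,
        normalized=True,
    )


def average_fisher(
    profile: FisherProfile,
    bounds: TimescaleBounds,
    n_grid: int = 2001,
    max_uncovered_mass: float = 0.02,
) -> float:
    """Average decoding accuracy ``<F> = int F(s) f_log10B(s) ds``.

    The integral runs over the intersection of the blank-distribution
    support ``[log10 tau, log10 T_B]`` with the profile support, by
    trapezoid on a refined grid with the profile linearly interpolated.  If
    the blank distribution puts more than ``max_uncovered_mass`` of its
    probability outside the profile support (e.g. a mismatched distance
    longer than the matching one), an error names the uncovered range —
    empirical profiles only ever miss a vanishing sliver at the sample
    extremes.
    """
    lo_b, hi_b = math.log10(bounds.tau), math.log10(bounds.T_B)
    lo_p, hi_p = profile.support
    lo, hi = max(lo_b, lo_p), min(hi_b, hi_p)
    if hi <= lo:
        raise ValueError(
            f"blank-distribution support [{lo_b:.4f}, {hi_b:.4f}] does not "
            f"overlap profile support [{lo_p:.4f}, {hi_p:.4f}]"
        )
    covered = float(log_blank_cdf(hi, bounds) - log_blank_cdf(lo, bounds))
    if 1.0 - covered > max_uncovered_mass:
        raise ValueError(
            "blank-distribution support exceeds the Fisher profile support: "
            f"uncovered range [{lo_b:.4f}, {lo:.4f}] U [{hi:.4f}, {hi_b:.4f}] "
            f"carries {1.0 - covered:.3f} probability mass"
        )
    s = np.linspace(lo, hi, n_grid)
    integrand = profile.interp(s) * log_blank_density(s, bounds)
    return float(np.trapezoid(integrand, s))


@dataclass
class AvgFisherComparison:
    """Matched-vs-mismatched average Fisher information.

    ``table`` has one row per encoder's matching distance and one column per
    applied (shorter or equal) distance; entries above the diagonal are NaN
    since longer distances leave the Fisher profile undefined on part of the
    blank range.  ``matched_best[m]`` flags whether the matched (diagonal)
    entry is the row maximum.
    """

    table: pd.DataFrame
    matched_best: pd.Series


def matched_vs_mismatched(
    profiles: Mapping[float, FisherProfile],
    bounds: Mapping[float, TimescaleBounds],
) -> AvgFisherComparison:
    """Average each distance's Fisher profile under matched and shorter-
    distance plume statistics (lower-triangular table)."""
    distances = sorted(profiles)
    table = pd.DataFrame(
        np.nan, index=pd.Index(distances, name="matching_d"),
        columns=pd.Index(distances, name="applied_d"),
    )
    for m in distances:
        for d in distances:
            if d > m:
                continue
            try:
                table.loc[m, d] = average_fisher(profiles[m], bounds[d])
            except ValueError:
                table.loc[m, d] = np.nan
    matched_best = pd.Series(
        {
            m: bool(np.nanmax(table.loc[m].to_numpy()) == table.loc[m, m])
            for m in distances
            if np.isfinite(table.loc[m, m])
        }
    )
    return AvgFisherComparison(table=table, matched_best=matched_best)


def median_log_blank(bounds: TimescaleBounds) -> float:
    """``alpha(0.5)``: log10 of the median blank duration (closed form)."""
    return math.log10(blank_dist(bounds).median())


@dataclass
class JeffreysPrior:
    """Optimal stimulus distribution ``p_J ∝ sqrt(F)`` on the short-blank half.

    ``density`` is unit-normalized on the support ``[log10 tau, alpha(0.5)]``
    (used for quantile comparison); ``density_printed`` uses the constant
    ``c = 2 int sqrt(F)`` so that it integrates to 1/2 on the half-support —
    both conventions are exposed and labelled.
    """

    grid: np.ndarray
    density: np.ndarray
    density_printed: np.ndarray
    c: float
    support: tuple[float, float]
    alpha_median: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def jeffreys_prior(
    profile: FisherProfile,
    bounds: TimescaleBounds,
    n_grid: int = 1001,
    coverage_tol: float = 0.02,
) -> JeffreysPrior:
    """Jeffreys prior derived from a Fisher profile.

    ``p_J(s) = sqrt(F(s)) / c`` with ``c = 2 int_{log10 tau}^{alpha(0.5)}
    sqrt(F) ds`` (printed convention, integrating to 1/2), alongside the
    unit-normalized density used for QQ comparison.  The profile must cover
    the support up to ``coverage_tol`` log10 units at the lower edge.
    """
    lower = math.log10(bounds.tau)
    alpha = median_log_blank(bounds)
    lo_p, hi_p = profile.support
    if lo_p > lower:
        if lo_p - lower > coverage_tol:
            raise ValueError(
                f"profile support starts at {lo_p:.4f}, above log10 tau = "
                f"{lower:.4f} by more than coverage_tol={coverage_tol}"
            )
        lower = lo_p
    if hi_p < alpha - coverage_tol:
        raise ValueError(
            f"profile support ends at {hi_p:.4f}, below the blank log-median "
            f"alpha(0.5) = {alpha:.4f}"
        )
    upper = min(alpha, hi_p)
    grid = np.linspace(lower, upper, n_grid)
    sqrtF = np.sqrt(profile.interp(grid))
    Z = float(np.trapezoid(sqrtF, grid))
    if Z <= 0:
        raise ValueError("Fisher information vanishes on the Jeffreys support")
    c = 2.0 * Z
    return JeffreysPrior(
        grid=grid,
        density=sqrtF / Z,
        density_printed=sqrtF / c,
        c=c,
        support=(lower, upper),
        alpha_median=alpha,
    )


@dataclass
class QQResult:
    """Quantile-quantile comparison of the Jeffreys prior vs real blanks."""

    levels: np.ndarray
    predicted: np.ndarray
    real: np.ndarray
    max_abs_dev: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "predicted": self.predicted, "real": self.real}
        )


def qq_compare(
    prior: JeffreysPrior,
    bounds: TimescaleBounds,
    levels: Optional[np.ndarray] = None,
) -> QQResult:
    """Compare quantiles of the estimated Jeffreys prior with the real
    blank-duration distribution conditioned on ``s <= alpha(0.5)``.

    The real conditional quantile at level p is the unconditional blank
    quantile at ``p/2`` (log10 scale); the predicted quantile inverts the
    prior's numeric CDF.  Returns the pairs and the maximum absolute
    deviation in log10 units.
    """
    if levels is None:
        levels = np.round(np.arange(0.01, 1.00, 0.01), 10)
    levels = np.asarray(levels, dtype=float)
    cdf = cumulative_trapezoid(prior.density, prior.grid, initial=0.0)
    cdf /= cdf[-1]
    predicted = np.interp(levels, cdf, prior.grid)
    real = np.log10(blank_dist(bounds).quantile(levels * 0.5))
    dev = float(np.max(np.abs(predicted - real)))
    return QQResult(levels=levels, predicted=predicted, real=real, max_abs_dev=dev)


def mode_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation of Fisher-profile modes vs blank-density modes
    across (distance, dose) conditions."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise ValueError("need at least 3 (FI mode, distribution mode) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("mode correlation undefined: zero variance in a coordinate")
    return float(pearsonr(x, y).statistic)


def reparameterize(
    grid: np.ndarray,
    F: np.ndarray,
    f: np.ndarray,
    phi: Callable,
    phi_prime: Callable,
):
    """Transform a Fisher profile and a stimulus density under a smooth
    monotone rescaling ``z = phi(s)``.

    Fisher information transforms with the squared Jacobian,
    ``F_z(phi(s)) = F(s)/phi'(s)^2``, a density with the Jacobian,
    ``f_z(phi(s)) = f(s)/phi'(s)``; when ``F ∝ f^2`` the two modes coincide
    in any parameterization.  Test utility; returns (new_grid, F_new, f_new).
    """
    grid = np.asarray(grid, dtype=float)
    jac = np.asarray(phi_prime(grid), dtype=float)
    if np.any(jac <= 0):
        raise ValueError("phi must be strictly increasing (phi' > 0)")
    return np.asarray(phi(grid), dtype=float), F / jac**2, f / jac
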