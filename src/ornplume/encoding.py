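"""Duration-rate encoding model: response extraction, smoothing-spline mean
and robust smoothed variance.

The encoding model of a whiff encounter is the *duration-rate relationship*:
the spike count ``r`` in a fixed window after the (latency-corrected) whiff
onset as a function of ``s = log10`` of the preceding blank duration.  The
mean curve ``gamma(s)`` is a cubic smoothing spline, i.e. the minimizer of

    sum_i [r_i - gamma(s_i)]^2 + lambda * int gamma''(s)^2 ds,

with the penalty ``lambda`` tuned so that the trace of the smoother matrix
(effective degrees of freedom) hits a target of about 3.  The response
variance ``sigma^2(s)`` is estimated robustly as ``(IQR/1.349)^2`` over
sliding segments of 10 ordered responses and smoothed by tricube-weighted
local linear regression spanning 90% of the data range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import make_smoothing_spline
from scipy.linalg import solve
from scipy.optimize import brentq

from .orn import SpikeTrainRecording

__all__ = [
    "SplineFit",
    "DurationRateFit",
    "extract_responses",
    "pool_samples",
    "extract_group_responses",
    "fit_duration_rate",
    "robust_variance_points",
    "smooth_variance",
    "fit_encoding_model",
    "natural_spline_penalty",
]

SAMPLE_COLUMNS = ["s", "r", "onset", "recording_id"]


def extract_responses(
    recording: SpikeTrainRecording,
    theta: float,
    window: float = 0.150,
    analysis_start: float = 100.0,
    analysis_end: float = 500.0,
) -> pd.DataFrame:
    """Extract (s, r) response samples from one recording.

    For each whiff with a complete preceding blank and onset within
    ``[analysis_start, analysis_end]`` (the adjusted-state portion of the
    recording), ``r`` counts spikes in the latency-corrected window
    ``[onset+theta, onset+theta+window)`` and ``s = log10`` of the preceding
    blank duration.  Returns a DataFrame with columns s, r, onset,
    recording_id.
    """
    if theta < 0:
        raise ValueError(f"latency theta must be >= 0, got {theta}")
    if analysis_start >= recording.sequence.total_duration:
        warnings.warn(
            "analysis interval lies outside the recording; no responses extracted",
            stacklevel=2,
        )
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    spikes = recording.spikes
    rows = []
    for onset, _dur, blank in recording.sequence.whiff_events():
        if blank is None or not (analysis_start <= onset <= analysis_end):
            continue
        lo = onset + theta
        hi = lo + window
        r = int(
            np.searchsorted(spikes, hi, side="left")
            - np.searchsorted(spikes, lo, side="left")
        )
        rows.append((np.log10(blank), r, onset, recording.neuron_id))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def pool_samples(samples: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-recording samples and sort by s (stable)."""
    frames = [f for f in samples if len(f)]
    if not frames:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    pooled = pd.concat(frames, ignore_index=True)
    return pooled.sort_values("s", kind="stable", ignore_index=True)


def extract_group_responses(
    recordings: Iterable[SpikeTrainRecording],
    theta: float,
    window: float = 0.150,
    analysis_start: float = 100.0,
    analysis_end: float = 500.0,
) -> pd.DataFrame:
    """Extract and pool responses across a (distance, dose) group."""
    return pool_samples(
        extract_responses(rec, theta, window, analysis_start, analysis_end)
        for rec in recordings
    )


# ---------------------------------------------------------------------------
# Cubic smoothing spline with trace-targeted penalty
# ---------------------------------------------------------------------------


def natural_spline_penalty(x: np.ndarray) -> np.ndarray:
    """Roughness penalty matrix K with ``int g''^2 = g^T K g`` for the natural
    cubic spline interpolating values ``g`` at strictly increasing knots ``x``
    (Reinsch construction: K = D^T C^{-1} D with banded D, C)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("penalty needs at least 3 knots")
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    C = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        C[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            C[i, i + 1] = h[i + 1] / 6.0
            C[i + 1, i] = h[i + 1] / 6.0
    return D.T @ solve(C, D, assume_a="pos")


class _SmootherTrace:
    """Exact smoother-matrix trace of the penalized least-squares fit.

    For data with distinct abscissas ``x`` carrying multiplicity weights
    ``w``, the trace of the full-data smoother at penalty ``lam`` is

        df(lam) = m - lam * tr[(C + lam G)^{-1} G],   G = D W^{-1} D^T,

    with the banded Reinsch matrices D (second differences over knot
    spacings) and C; G is pentadiagonal, so each evaluation is a banded
    Cholesky solve.  df is monotone decreasing in lam, from m (number of
    distinct abscissas) at lam=0 to 2 (straight-line null space) as
    lam -> inf.
    """

    def __init__(self, x: np.ndarray, w: np.ndarray):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        m = len(x)
        if m < 3:
            raise ValueError("smoother trace needs at least 3 distinct knots")
        h = np.diff(x)
        d0 = 1.0 / h[:-1]
        d2 = 1.0 / h[1:]
        d1 = -(d0 + d2)
        k = m - 2
        G = np.zeros((k, k))
        iw = 1.0 / w
        idx = np.arange(k)
        G[idx, idx] = d0**2 * iw[:-2] + d1**2 * iw[1:-1] + d2**2 * iw[2:]
        if k > 1:
            off1 = d1[:-1] * d0[1:] * iw[1:k] + d2[:-1] * d1[1:] * iw[2 : k + 1]
            G[idx[:-1], idx[:-1] + 1] = off1
            G[idx[:-1] + 1, idx[:-1]] = off1
        if k > 2:
            off2 = d2[:-2] * d0[2:] * iw[2:-2]
            G[idx[:-2], idx[:-2] + 2] = off2
            G[idx[:-2] + 2, idx[:-2]] = off2
        C_band = np.zeros((3, k))  # upper banded storage for solveh_banded
        C_band[2] = (h[:-1] + h[1:]) / 3.0
        C_band[1, 1:] = h[1:-1] / 6.0
        G_band = np.zeros((3, k))
        G_band[2] = G[idx, idx]
        if k > 1:
            G_band[1, 1:] = G[idx[:-1], idx[:-1] + 1]
        if k > 2:
            G_band[0, 2:] = G[idx[:-2], idx[:-2] + 2]
        self.m = m
        self._G = G
        self._C_band = C_band
        self._G_band = G_band

    def df(self, lam: float) -> float:
        from scipy.linalg import solveh_banded

        M_band = self._C_band + lam * self._G_band
        X = solveh_banded(M_band, self._G, lower=False)
        return float(self.m - lam * np.trace(X))


@dataclass
class SplineFit:
    """Fitted mean-response spline with its penalty diagnostics."""

    gamma: Callable
    gamma_prime: Callable
    lam: float
    trace: float
    knots: np.ndarray
    support: tuple[float, float]


def _merge_duplicates(s: np.ndarray, r: np.ndarray, resolution: float = 1e-3):
    """Merge duplicate and near-duplicate abscissas into weighted means.

    Abscissas falling in the same cell of width ``resolution * range(s)``
    are pooled with multiplicity weights.  This reflects the finite time
    resolution of the stimulus delivery and keeps the Reinsch penalty
    matrices well conditioned (knot gaps enter as 1/h^3).
    """
    order = np.argsort(s, kind="stable")
    s, r = s[order], r[order]
    span = s[-1] - s[0]
    if span <= 0:
        raise ValueError("degenerate s spread: all abscissas coincide")
    cell = np.round((s - s[0]) / (resolution * span)).astype(np.int64)
    _, inverse, counts = np.unique(cell, return_inverse=True, return_counts=True)
    xsum = np.bincount(inverse, weights=s)
    ysum = np.bincount(inverse, weights=r)
    return xsum / counts, ysum / counts, counts.astype(float)


def fit_duration_rate(
    samples: pd.DataFrame,
    target_trace: float = 3.0,
    trace_tol: float = 0.1,
) -> SplineFit:
    """Fit the duration-rate curve gamma(s) by a cubic smoothing spline.

    The penalty ``lambda`` is selected by a monotone root search (Brent on
    log lambda) so the exact full-data smoother-matrix trace — computed via
    the banded Reinsch identity, see :class:`_SmootherTrace` — lands within
    ``trace_tol`` of ``target_trace``.  The derivative comes analytically
    from the fitted piecewise cubic.  Duplicate abscissas are merged with
    multiplicity weights (the trace accounts for them).
    """
    if len(samples) < 10:
        raise ValueError(f"need at least 10 samples, got {len(samples)}")
    s = samples["s"].to_numpy(dtype=float)
    r = samples["r"].to_numpy(dtype=float)
    if len(np.unique(s)) < 5:
        raise ValueError(
            "degenerate s spread: need at least 5 distinct log-duration values"
        )
    xu, y, w = _merge_duplicates(s, r)
    tracer = _SmootherTrace(xu, w)
    n_knots = len(xu)
    if not 2.0 < target_trace < n_knots:
        raise ValueError(
            f"target trace {target_trace} unattainable with {n_knots} knots"
        )

    def gap(log_lam: float) -> float:
        return tracer.df(10.0**log_lam) - target_trace

    lo, hi = -16.0, 6.0
    while gap(hi) > 0 and hi < 30:
        hi += 4.0
    while gap(lo) < 0 and lo > -40:
        lo -= 4.0
    log_lam = brentq(gap, lo, hi, xtol=1e-10)
    lam = 10.0**log_lam
    trace = tracer.df(lam)
    if abs(trace - target_trace) > trace_tol:
        raise RuntimeError(
            f"penalty search failed: trace {trace:.3f} vs target {target_trace}"
        )
    spline = make_smoothing_spline(xu, y, w=w, lam=lam)
    return SplineFit(
        gamma=spline,
        gamma_prime=spline.derivative(),
        lam=lam,
        trace=trace,
        knots=xu,
        support=(float(s.min()), float(s.max())),
    )


# ---------------------------------------------------------------------------
# Robust variance profile
# ---------------------------------------------------------------------------


def robust_variance_points(
    samples: pd.DataFrame, segment_size: int = 10
) -> pd.DataFrame:
    """Raw robust variance over sliding segments of ordered responses.

    Responses are ordered by s; every window of ``segment_size`` consecutive
    responses (step 1) yields ``variance_raw = (IQR(r)/1.349)^2`` with
    type-7 (linear interpolation) quartiles, located at the median of the
    window's s values.  Returns a DataFrame (s_center, variance_raw).
    """
    if len(samples) < segment_size:
        raise ValueError(
            f"need at least segment_size={segment_size} samples, got {len(samples)}"
        )
    ordered = samples.sort_values("s", kind="stable")
    s = ordered["s"].to_numpy(dtype=float)
    r = ordered["r"].to_numpy(dtype=float)
    rw = sliding_window_view(r, segment_size)
    sw = sliding_window_view(s, segment_size)
    q25, q75 = np.percentile(rw, [25, 75], axis=1)  # 'linear' = type 7
    variance_raw = ((q75 - q25) / 1.349) ** 2
    s_center = np.median(sw, axis=1)
    return pd.DataFrame({"s_center": s_center, "variance_raw": variance_raw})


def smooth_variance(
    points: pd.DataFrame,
    span_fraction: float = 0.9,
    floor: float = 1e-6,
) -> Callable:
    """Smooth raw variances by tricube-weighted local linear regression.

    At each query ``s`` a straight line is fitted to the
    (s_center, variance_raw) points with weights ``w(u) = (1-|u|^3)^3`` for
    ``|u| <= 1``, ``u = (s_center - s)/h``, where the bandwidth
    ``h = span_fraction * range(s_center) / 2`` makes the kernel's full
    support span ``span_fraction`` of the data range.  The returned function
    evaluates the local line at ``s``, floored at a small positive epsilon
    so downstream Fisher ratios stay finite.
    """
    if len(points) < 2:
        raise ValueError(f"need at least 2 variance points, got {len(points)}")
    sc = points["s_center"].to_numpy(dtype=float)
    v = points["variance_raw"].to_numpy(dtype=float)
    h = span_fraction * (sc.max() - sc.min()) / 2.0
    if h == 0:  # single cluster of identical abscissas -> constant fit
        const = max(float(v.mean()), floor)

        def sigma2_const(s):
            s = np.asarray(s, dtype=float)
            out = np.full_like(s, const)
            return out if out.ndim else float(out)

        return sigma2_const

    def sigma2(s):
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty_like(s_arr)
        for i, si in enumerate(s_arr):
            u = (sc - si) / h
            w = np.where(np.abs(u) < 1.0, (1.0 - np.abs(u) ** 3) ** 3, 0.0)
            wsum = w.sum()
            if wsum <= 0:
                raise ValueError(
                    f"all tricube weights vanish at query s={si:g}; "
                    "query lies outside the smoothing span"
                )
            xw = sc - si
            sw_ = w.sum()
            sx = np.dot(w, xw)
            sxx = np.dot(w, xw * xw)
            sy = np.dot(w, v)
            sxy = np.dot(w, xw * v)
            det = sw_ * sxx - sx * sx
            if det <= 1e-300:  # weighted points degenerate -> weighted mean
                out[i] = sy / sw_
            else:
                out[i] = (sxx * sy - sx * sxy) / det  # intercept = value at si
        out = np.maximum(out, floor)
        return out if np.ndim(s) else float(out[0])

    return sigma2


@dataclass
class DurationRateFit:
    """Complete encoding-model fit: mean curve, derivative and variance."""

    gamma: Callable
    gamma_prime: Callable
    sigma2: Callable
    support: tuple[float, float]
    lam: float
    trace: float
    grid: np.ndarray
    n_samples: int


def fit_encoding_model(
    samples: pd.DataFrame,
    target_trace: float = 3.0,
    segment_size: int = 10,
    span_fraction: float = 0.9,
    grid_size: int = 201,
    variance_floor: float = 1e-6,
) -> DurationRateFit:
    """Fit mean and variance profiles and bundle them with a shared grid."""
    spline = fit_duration_rate(samples, target_trace=target_trace)
    points = robust_variance_points(samples, segment_size=segment_size)
    sigma2 = smooth_variance(points, span_fraction=span_fraction, floor=variance_floor)
    lo, hi = spline.support
    grid = np.linspace(lo, hi, grid_size)
    return DurationRateFit(
        gamma=spline.gamma,
        gamma_prime=spline.gamma_prime,
        sigma2=sigma2,
        support=spline.support,
        lam=spline.lam,
        trace=spline.trace,
        grid=grid,
        n_samples=len(samples),
    )
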