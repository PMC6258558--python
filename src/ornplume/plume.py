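"""Stimulus-timescale statistics of a turbulent pheromone plume.

At a fixed point downwind of an odor source, turbulence breaks the signal
into *whiffs* (odor present) and *blanks* (clean air).  Both durations follow
a truncated power law with density ``x^(-3/2)`` between a shortest timescale
``tau`` and a longest one that grows with downwind distance: ``T_W = d/U``
for whiffs and ``T_B = T_W (1/chi - 1)`` for blanks, where ``chi`` is the
intermittency factor (fraction of time odor is detectable).  This module
provides those distributions in closed form (density, CDF, quantile, both on
the duration axis and on the decadic-log axis used throughout the analysis)
and a generator of alternating whiff/blank stimulus sequences that emulate
the valve-driven delivery protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "PlumeParams",
    "TimescaleBounds",
    "TruncatedPowerLawDist",
    "StimulusSequence",
    "WHIFF",
    "BLANK",
    "STANDARD_DISTANCES",
    "derive_timescales",
    "blank_dist",
    "whiff_dist",
    "blank_density",
    "whiff_density",
    "log_blank_density",
    "log_blank_cdf",
    "log_blank_mode",
    "duration_quantile",
    "sample_durations",
    "generate_sequence",
    "whiff_time_fraction",
]

_LN10 = math.log(10.0)

WHIFF = "whiff"
BLANK = "blank"

#: Virtual downwind distances (m) used in the stimulation protocol.
STANDARD_DISTANCES = (8.0, 16.0, 32.0, 64.0, 128.0)


@dataclass(frozen=True)
class PlumeParams:
    """Physical parameters of the plume model.

    Parameters
    ----------
    d : float
        Downwind distance from the source (m).
    U : float
        Mean wind speed (m/s).
    dU : float
        Wind-speed fluctuation magnitude (m/s).
    a : float
        Source size (m).
    chi : float
        Intermittency factor, the fraction of time odor is detectable
        (0 < chi < 1).
    tau_override : float, optional
        Replace the derived shortest timescale ``tau`` with a custom value.
        The derived formula ``tau = a^2 d / [d dU^2]`` is distance
        independent (``d`` cancels); the override hook lets studies impose a
        distance-dependent shortest eddy timescale.
    """

    d: float
    U: float = 1.0
    dU: float = 0.1
    a: float = 0.1
    chi: float = 0.4
    tau_override: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("d", "U", "dU", "a", "chi"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(
                    f"PlumeParams.{name} must be strictly positive, got {value!r}"
                )
        if not self.chi < 1:
            raise ValueError(f"intermittency chi must be < 1, got {self.chi!r}")
        if self.tau_override is not None and not self.tau_override > 0:
            raise ValueError(
                f"tau_override must be strictly positive, got {self.tau_override!r}"
            )


@dataclass(frozen=True)
class TimescaleBounds:
    """Shortest/longest whiff and blank timescales (seconds)."""

    tau: float
    T_W: float
    T_B: float

    def __post_init__(self) -> None:
        if not 0 < self.tau < self.T_W:
            raise ValueError(f"need 0 < tau < T_W, got tau={self.tau}, T_W={self.T_W}")
        if not self.tau < self.T_B:
            raise ValueError(f"need tau < T_B, got tau={self.tau}, T_B={self.T_B}")


def derive_timescales(params: PlumeParams) -> TimescaleBounds:
    """Derive ``(tau, T_W, T_B)`` from the physical plume parameters.

    ``tau = a^2 d / [d dU^2]`` (note ``d`` cancels, so the printed formula is
    distance independent), ``T_W = d/U`` and ``T_B = T_W (1/chi - 1)``.  A
    ``tau_override`` on the params replaces the derived ``tau``.
    """
    if params.tau_override is not None:
        tau = float(params.tau_override)
    else:
        tau = params.a**2 * params.d / (params.d * params.dU**2)
    T_W = params.d / params.U
    T_B = T_W * (1.0 / params.chi - 1.0)
    return TimescaleBounds(tau=tau, T_W=T_W, T_B=T_B)


@dataclass(frozen=True)
class TruncatedPowerLawDist:
    """Duration distribution with density ``x^(-3/2)`` truncated to ``[tau, T]``.

    The normalized density is ``f(x) = x^(-3/2) / [2 (1/sqrt(tau) - 1/sqrt(T))]``;
    the CDF and quantile are available in closed form, and the mean is
    ``sqrt(tau * T)``.
    """

    tau: float
    T: float

    def __post_init__(self) -> None:
        if not 0 < self.tau < self.T:
            raise ValueError(f"need 0 < tau < T, got tau={self.tau}, T={self.T}")

    @property
    def _norm(self) -> float:
        return 2.0 * (self.tau**-0.5 - self.T**-0.5)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.tau) & (x <= self.T)
        out = np.zeros_like(x)
        xs = np.where(inside, x, 1.0)
        out = np.where(inside, xs**-1.5 / self._norm, 0.0)
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.tau, self.T)
        out = (self.tau**-0.5 - xc**-0.5) / (self.tau**-0.5 - self.T**-0.5)
        return out if out.ndim else float(out)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile probabilities must lie in [0, 1]")
        inv_sqrt = self.tau**-0.5 - u * (self.tau**-0.5 - self.T**-0.5)
        out = inv_sqrt**-2.0
        return out if out.ndim else float(out)

    def mean(self) -> float:
        return math.sqrt(self.tau * self.T)

    def median(self) -> float:
        return float(self.quantile(0.5))


def blank_dist(bounds: TimescaleBounds) -> TruncatedPowerLawDist:
    """Blank-duration distribution on ``[tau, T_B]``."""
    return TruncatedPowerLawDist(bounds.tau, bounds.T_B)


def whiff_dist(bounds: TimescaleBounds) -> TruncatedPowerLawDist:
    """Whiff-duration distribution on ``[tau, T_W]``."""
    return TruncatedPowerLawDist(bounds.tau, bounds.T_W)


def blank_density(x, bounds: TimescaleBounds):
    """Blank-duration density (1/s); zero outside ``[tau, T_B]``."""
    return blank_dist(bounds).pdf(x)


def whiff_density(x, bounds: TimescaleBounds):
    """Whiff-duration density (1/s); zero outside ``[tau, T_W]``."""
    return whiff_dist(bounds).pdf(x)


def log_blank_density(s, bounds: TimescaleBounds):
    """Density of ``log10`` blank duration, per log10 unit.

    Change of variables ``Y = log10 B`` gives
    ``f(s) = 10^(-s/2) ln(10) / [2 (1/sqrt(tau) - 1/sqrt(T_B))]`` on
    ``[log10 tau, log10 T_B]``; strictly decreasing, so the mode sits at
    ``log10 tau``.
    """
    s = np.asarray(s, dtype=float)
    lo, hi = math.log10(bounds.tau), math.log10(bounds.T_B)
    inside = (s >= lo) & (s <= hi)
    norm = 2.0 * (bounds.tau**-0.5 - bounds.T_B**-0.5)
    out = np.where(inside, 10.0 ** (-s / 2.0) * _LN10 / norm, 0.0)
    return out if out.ndim else float(out)


def log_blank_cdf(s, bounds: TimescaleBounds):
    """CDF of ``log10`` blank duration."""
    s = np.asarray(s, dtype=float)
    out = blank_dist(bounds).cdf(10.0**s)
    return out if np.ndim(out) else float(out)


def log_blank_mode(bounds: TimescaleBounds) -> float:
    """Mode of the log10 blank-duration density (= ``log10 tau``)."""
    return math.log10(bounds.tau)


def duration_quantile(u, dist: TruncatedPowerLawDist):
    """Inverse CDF of a truncated power-law duration distribution."""
    return dist.quantile(u)


def sample_durations(n: int, dist: TruncatedPowerLawDist, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. durations by inverse-transform sampling."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return dist.quantile(rng.uniform(size=int(n)))


@dataclass
class StimulusSequence:
    """Alternating whiff/blank event train (the virtual plume).

    Events are contiguous and non-overlapping; ``onsets`` are strictly
    increasing and each event's onset equals the previous event's end.  The
    final event may be truncated by the total duration, in which case
    ``final_truncated`` is set and downstream stages exclude responses whose
    preceding blank is that event.
    """

    onsets: np.ndarray
    durations: np.ndarray
    kinds: np.ndarray
    total_duration: float
    params: Optional[PlumeParams] = None
    seed: Optional[int] = None
    whiff_cap: Optional[float] = None
    final_truncated: bool = False

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.kinds = np.asarray(self.kinds)
        n = len(self.onsets)
        if not (len(self.durations) == n and len(self.kinds) == n):
            raise ValueError("onsets, durations and kinds must have equal length")
        if n == 0:
            raise ValueError("stimulus sequence must contain at least one event")
        if np.any(self.durations <= 0):
            raise ValueError("event durations must be strictly positive")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        ends = self.onsets[:-1] + self.durations[:-1]
        # tolerance matches the 1e-6 s serialization precision (well below
        # the 1 ms valve resolution); generated sequences are exact
        if not np.allclose(ends, self.onsets[1:], rtol=0.0, atol=2e-6):
            raise ValueError("events must be contiguous (no gaps or overlaps)")
        kinds = set(self.kinds.tolist())
        if not kinds <= {WHIFF, BLANK}:
            raise ValueError(f"unknown event kinds: {kinds - {WHIFF, BLANK}}")
        alternating = all(
            self.kinds[i] != self.kinds[i + 1] for i in range(n - 1)
        )
        if not alternating:
            raise ValueError("whiff and blank events must alternate")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    @property
    def events(self):
        """Events as a list of ``(onset_s, duration_s, kind)`` tuples."""
        return list(zip(self.onsets.tolist(), self.durations.tolist(), self.kinds.tolist()))

    def whiff_events(self) -> Iterator[tuple[float, float, Optional[float]]]:
        """Yield ``(onset, duration, preceding_blank_duration)`` per whiff.

        ``preceding_blank_duration`` is ``None`` when the whiff has no
        complete preceding blank (no preceding event, or the preceding blank
        is the truncated final event — impossible mid-sequence but possible
        for ingested recordings).
        """
        n = self.n_events
        for i in range(n):
            if self.kinds[i] != WHIFF:
                continue
            blank = None
            if i > 0 and self.kinds[i - 1] == BLANK:
                if not (self.final_truncated and i - 1 == n - 1):
                    blank = float(self.durations[i - 1])
            yield float(self.onsets[i]), float(self.durations[i]), blank


def generate_sequence(
    params: PlumeParams,
    total_duration: float,
    seed,
    whiff_cap="auto",
    max_attempts: int = 1000,
) -> StimulusSequence:
    """Generate an alternating blank/whiff sequence covering ``total_duration``.

    Durations are drawn independently from the blank and whiff truncated
    power laws; the sequence starts with a blank (so every whiff onset is
    preceded by a measurable blank) and the final event is truncated to the
    total duration and flagged.  When ``whiff_cap`` is set (``"auto"`` maps
    to 30 s for d in {64, 128} m, else no cap, mirroring the removal of
    extremely long puffs at the far distances), whole sequences containing
    any whiff longer than the cap are rejected and regenerated.
    """
    if not total_duration > 0:
        raise ValueError(f"total_duration must be positive, got {total_duration!r}")
    bounds = derive_timescales(params)
    if whiff_cap == "auto":
        cap = 30.0 if params.d in (64, 64.0, 128, 128.0) else None
    else:
        cap = whiff_cap
    b_dist = blank_dist(bounds)
    w_dist = whiff_dist(bounds)
    rng = np.random.default_rng(seed)
    seed_int = int(seed) if np.isscalar(seed) else None

    for _attempt in range(max_attempts):
        onsets: list[float] = []
        durations: list[float] = []
        kinds: list[str] = []
        t = 0.0
        kind = BLANK
        truncated = False
        while t < total_duration:
            u = rng.uniform()
            dist = b_dist if kind == BLANK else w_dist
            dur = float(dist.quantile(u))
            if t + dur >= total_duration:
                dur = total_duration - t
                truncated = True
            onsets.append(t)
            durations.append(dur)
            kinds.append(kind)
            t += dur
            kind = WHIFF if kind == BLANK else BLANK
        if cap is not None:
            whiffs = [d for d, k in zip(durations, kinds) if k == WHIFF]
            if any(d > cap for d in whiffs):
                continue
        return StimulusSequence(
            onsets=np.array(onsets),
            durations=np.array(durations),
            kinds=np.array(kinds),
            total_duration=float(total_duration),
            params=params,
            seed=seed_int,
            whiff_cap=cap,
            final_truncated=truncated,
        )
    raise RuntimeError(
        f"failed to generate a sequence satisfying whiff cap {cap} s "
        f"within {max_attempts} attempts (d={params.d} m)"
    )


def whiff_time_fraction(sequence: StimulusSequence) -> float:
    """Realized intermittency: fraction of total time covered by whiffs."""
    whiff_time = float(sequence.durations[sequence.kinds == WHIFF].sum())
    return whiff_time / sequence.total_duration
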