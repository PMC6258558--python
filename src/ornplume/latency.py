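"""Nonparametric response-latency estimation from spike trains.

The delivery apparatus introduces a latency ``theta`` between the valve
opening (whiff onset in the stimulus sequence) and the pheromone reaching
the sensillum.  The estimator compares two empirical CDFs collected at whiff
onsets: F_W of the backward intervals ``w`` (last spike during the preceding
blank to onset) and F_T of the forward intervals ``t`` (onset to first
subsequent spike).  Below the true latency both intervals are gaps of the
same spontaneous process, so ``D(t) = F_T(t) - F_W(t)`` stays near zero;
above it the evoked response makes forward intervals stochastically shorter
and D rises.  The estimate is the largest point below the first peak of D at
which D is still <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .orn import SpikeTrainRecording

__all__ = [
    "LatencyIntervals",
    "LatencyEstimate",
    "collect_intervals",
    "empirical_cdf",
    "estimate_latency",
]


@dataclass
class LatencyIntervals:
    """Paired backward (w) and forward (t) intervals around whiff onsets."""

    w: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.w.shape != self.t.shape:
            raise ValueError("w and t must be extracted pairwise (equal length)")
        if np.any(self.w < 0) or np.any(self.t < 0):
            raise ValueError("intervals must be non-negative")

    @property
    def n(self) -> int:
        return len(self.w)


@dataclass(frozen=True)
class LatencyEstimate:
    theta_hat: float
    t_tilde: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.theta_hat <= self.t_tilde:
            raise ValueError("need 0 <= theta_hat <= t_tilde")


def collect_intervals(recordings: Iterable[SpikeTrainRecording]) -> LatencyIntervals:
    """Pool (w, t) interval pairs across a group of recordings.

    For each whiff onset: ``w`` is the interval from the last spike strictly
    before the onset — provided it falls within the preceding blank — to the
    onset, and ``t`` the interval from the onset to the first spike strictly
    after it.  Onsets lacking either spike are skipped.
    """
    ws: list[float] = []
    ts: list[float] = []
    for rec in recordings:
        spikes = rec.spikes
        seq = rec.sequence
        for i in range(seq.n_events):
            if seq.kinds[i] != "whiff" or i == 0 or seq.kinds[i - 1] != "blank":
                continue
            onset = float(seq.onsets[i])
            blank_start = float(seq.onsets[i - 1])
            j = np.searchsorted(spikes, onset, side="left")
            if j == 0:
                continue
            last = float(spikes[j - 1])
            if last < blank_start or last >= onset:
                continue
            k = np.searchsorted(spikes, onset, side="right")
            if k >= len(spikes):
                continue
            first = float(spikes[k])
            ws.append(onset - last)
            ts.append(first - onset)
    if not ws:
        raise ValueError("no whiff onset with both flanking spikes was found")
    return LatencyIntervals(w=np.array(ws), t=np.array(ts))


def empirical_cdf(sample: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Right-continuous empirical CDF: value k/n at the k-th order statistic."""
    xs = np.sort(np.asarray(sample, dtype=float))
    if xs.size == 0:
        raise ValueError("empirical CDF of an empty sample is undefined")
    n = len(xs)

    def cdf(x):
        out = np.searchsorted(xs, np.asarray(x, dtype=float), side="right") / n
        return out if np.ndim(x) else float(out)

    return cdf


def estimate_latency(intervals: LatencyIntervals) -> LatencyEstimate:
    """Estimate the response latency from pooled interval pairs.

    ``D(t) = F_T(t) - F_W(t)`` is evaluated on the pooled sample points of
    ``w`` and ``t`` plus 0 (the step functions change nowhere else),
    restricted to ``[0, max(t)]``.  The argmax point ``t~`` takes the
    smallest maximizer on plateaus; the estimate is the largest evaluation
    point ``<= t~`` with ``D <= 0`` (0 when none exists).
    """
    if intervals.n < 2:
        raise ValueError(f"need at least 2 interval pairs, got {intervals.n}")
    w, t = intervals.w, intervals.t
    t_n = float(t.max())
    points = np.unique(np.concatenate([[0.0], w, t]))
    points = points[points <= t_n]
    F_T = empirical_cdf(t)
    F_W = empirical_cdf(w)
    D = F_T(points) - F_W(points)
    idx = int(np.argmax(D))  # smallest maximizer on ties
    t_tilde = float(points[idx])
    admissible = points[(points <= t_tilde) & (D <= 1e-12)]
    theta_hat = float(admissible.max()) if admissible.size else 0.0
    return LatencyEstimate(theta_hat=theta_hat, t_tilde=t_tilde, n=intervals.n)
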