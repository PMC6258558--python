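"""Synthetic olfactory receptor neuron (ORN) spike trains with known encoders.

A parametric encoder maps the decadic log of the blank duration preceding a
whiff, ``s = log10(blank)``, to the expected spike count ``mu(s)`` in a fixed
response window after the whiff onset (plus a latency ``theta``).  Counts are
drawn from a Poisson or Gaussian noise family; spontaneous activity runs as a
homogeneous Poisson process at rate ``r0`` outside the response windows.
Because the encoder is known exactly, every downstream estimator (latency,
duration-rate fit, Fisher-information profile) can be validated against its
closed-form ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .plume import (
    PlumeParams,
    StimulusSequence,
    TimescaleBounds,
    blank_dist,
    generate_sequence,
    log_blank_density,
)

__all__ = [
    "EncoderSpec",
    "SpikeTrainRecording",
    "make_saturating_encoder",
    "make_jeffreys_matched_encoder",
    "analytic_fisher",
    "simulate_recording",
    "simulate_population",
]

POISSON = "poisson"
GAUSSIAN = "gaussian"


@dataclass
class EncoderSpec:
    """Parametric encoding model: blank log-duration -> response-window count.

    ``mu(s)`` is the expected spike count in the response window, ``theta``
    the response latency (s), ``r0`` the spontaneous rate (spikes/s) and
    ``window`` the response-window length (s).  ``mu_prime`` is the analytic
    derivative when available (used by :func:`analytic_fisher`); ``sigma2``
    is the count-variance function, required for the Gaussian noise family.
    """

    mu: Callable[[np.ndarray], np.ndarray]
    theta: float = 0.026
    r0: float = 5.0
    window: float = 0.150
    noise: str = POISSON
    sigma2: Optional[Callable[[np.ndarray], np.ndarray]] = None
    mu_prime: Optional[Callable[[np.ndarray], np.ndarray]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError(f"latency theta must be >= 0, got {self.theta}")
        if self.r0 < 0:
            raise ValueError(f"spontaneous rate r0 must be >= 0, got {self.r0}")
        if not self.window > 0:
            raise ValueError(f"response window must be positive, got {self.window}")
        if self.noise not in (POISSON, GAUSSIAN):
            raise ValueError(f"unsupported noise family: {self.noise!r}")
        if self.noise == GAUSSIAN and self.sigma2 is None:
            raise ValueError("gaussian noise family requires a sigma2 function")


def make_saturating_encoder(
    r_max: float,
    s_half: float,
    slope: float,
    r0: float = 5.0,
    theta: float = 0.026,
    window: float = 0.150,
    noise: str = POISSON,
    sigma2: Optional[Callable] = None,
) -> EncoderSpec:
    """Logistic (saturating) duration-rate encoder.

    ``mu(s) = window * [r0 + r_max / (1 + exp(-slope (s - s_half)))]`` —
    monotone increasing in ``s`` for positive slope, saturating at
    ``window * (r0 + r_max)``; the shape mimics measured duration-rate
    relationships where responses grow with the preceding blank duration.
    """
    if not r_max > 0:
        raise ValueError(f"r_max must be positive, got {r_max}")

    def mu(s):
        s = np.asarray(s, dtype=float)
        out = window * (r0 + r_max * expit(slope * (s - s_half)))
        return out if out.ndim else float(out)

    def mu_prime(s):
        s = np.asarray(s, dtype=float)
        p = expit(slope * (s - s_half))
        out = window * r_max * slope * p * (1.0 - p)
        return out if out.ndim else float(out)

    return EncoderSpec(
        mu=mu,
        mu_prime=mu_prime,
        theta=theta,
        r0=r0,
        window=window,
        noise=noise,
        sigma2=sigma2,
        description=(
            f"saturating(r_max={r_max}, s_half={s_half}, slope={slope}, "
            f"r0={r0}, theta={theta}, window={window})"
        ),
    )


def make_jeffreys_matched_encoder(
    bounds: TimescaleBounds,
    mu_min: float = 2.0,
    c: float = 6.0,
    r0: float = 5.0,
    theta: float = 0.026,
    window: float = 0.150,
) -> EncoderSpec:
    """Poisson encoder whose Fisher information matches the Jeffreys condition.

    Setting ``sqrt(mu(s)) = sqrt(mu_min) + (c/2) * CDF_log(s)``, where
    ``CDF_log`` is the cumulative of the log10 blank-duration density, makes
    the Poisson Fisher information ``F(s) = mu'(s)^2 / mu(s) = c^2 f(s)^2``
    with ``f`` the log-blank density — i.e. ``sqrt(F)`` is exactly
    proportional to the stimulus-timescale density, the optimal-population-
    coding (Jeffreys prior) relationship.
    """
    if not mu_min > 0:
        raise ValueError(f"mu_min must be positive, got {mu_min}")
    dist = blank_dist(bounds)
    sqrt_mu_min = np.sqrt(mu_min)

    def _sqrt_mu(s):
        s = np.asarray(s, dtype=float)
        return sqrt_mu_min + (c / 2.0) * dist.cdf(10.0**s)

    def mu(s):
        out = _sqrt_mu(s) ** 2
        return out if np.ndim(out) else float(out)

    def mu_prime(s):
        out = _sqrt_mu(s) * c * log_blank_density(s, bounds)
        return out if np.ndim(out) else float(out)

    return EncoderSpec(
        mu=mu,
        mu_prime=mu_prime,
        theta=theta,
        r0=r0,
        window=window,
        noise=POISSON,
        description=(
            f"jeffreys_matched(tau={bounds.tau}, T_B={bounds.T_B}, "
            f"mu_min={mu_min}, c={c}, r0={r0}, theta={theta})"
        ),
    )


def analytic_fisher(encoder: EncoderSpec, s):
    """Closed-form Fisher information of the encoder's noise family.

    Poisson: ``F(s) = mu'(s)^2 / mu(s)``; Gaussian with known variance:
    ``F(s) = mu'(s)^2 / sigma2(s)``.  Uses the analytic ``mu_prime`` when the
    encoder provides one, else a central difference.
    """
    s = np.asarray(s, dtype=float)
    if encoder.mu_prime is not None:
        mup = np.asarray(encoder.mu_prime(s), dtype=float)
    else:
        h = 1e-6
        mup = (np.asarray(encoder.mu(s + h)) - np.asarray(encoder.mu(s - h))) / (2 * h)
    if encoder.noise == POISSON:
        mu = np.asarray(encoder.mu(s), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(mu > 0, mup**2 / np.where(mu > 0, mu, 1.0), 0.0)
    elif encoder.noise == GAUSSIAN:
        var = np.asarray(encoder.sigma2(s), dtype=float)
        out = mup**2 / var
    else:  # pragma: no cover - guarded by EncoderSpec validation
        raise ValueError(f"unsupported noise family: {encoder.noise!r}")
    return out if out.ndim else float(out)


@dataclass
class SpikeTrainRecording:
    """Spike times paired with the stimulus sequence that evoked them."""

    spikes: np.ndarray
    sequence: StimulusSequence
    distance_label: Optional[float] = None
    dose_label: Optional[float] = None
    neuron_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        if self.spikes.size:
            if np.any(np.diff(self.spikes) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spikes[0] < 0 or self.spikes[-1] > self.sequence.total_duration:
                raise ValueError(
                    "spike times must lie within [0, total_duration] of the sequence"
                )


def _adaptation_gain(t, amplitude: float, tau_adapt: float):
    if amplitude == 0.0:
        return np.ones_like(np.asarray(t, dtype=float))
    return 1.0 + amplitude * np.exp(-np.asarray(t, dtype=float) / tau_adapt)


def simulate_recording(
    encoder: EncoderSpec,
    sequence: StimulusSequence,
    seed,
    neuron_id: Optional[str] = None,
    distance_label: Optional[float] = None,
    dose_label: Optional[float] = None,
    adapt_amplitude: float = 0.0,
    adapt_tau: float = 50.0,
) -> SpikeTrainRecording:
    """Simulate one ORN recording driven by a stimulus sequence.

    Spontaneous spikes arise as a homogeneous Poisson process at rate ``r0``
    during blanks and during whiff epochs outside the response window
    (including the latency gap ``[onset, onset+theta)``, since physically the
    odor has not yet arrived there).  For each whiff with a complete
    preceding blank of log-duration ``s``, a count is drawn from the noise
    family with mean ``mu(s)`` (optionally scaled by an adaptation gain
    ``1 + A exp(-onset/adapt_tau)``, default off) and placed uniformly in
    ``[onset+theta, onset+theta+window]``.  Whiffs with a truncated or absent
    preceding blank receive spontaneous activity only.  Reproducible given
    the seed: the random stream is consumed in a fixed order (spontaneous
    counts, spontaneous positions, response counts, response positions).
    """
    if encoder.window > derive_min_whiff(sequence):
        import warnings

        warnings.warn(
            "response window exceeds the shortest whiff in the sequence; "
            "response counts may straddle whiff ends",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    total = sequence.total_duration
    theta, window = encoder.theta, encoder.window

    # Spontaneous segments: blanks, plus whiff time outside response windows.
    seg_start: list[float] = []
    seg_len: list[float] = []
    resp_onset: list[float] = []
    resp_s: list[float] = []
    for i in range(sequence.n_events):
        onset = float(sequence.onsets[i])
        dur = float(sequence.durations[i])
        if sequence.kinds[i] == "blank":
            seg_start.append(onset)
            seg_len.append(dur)
            continue
        blank = None
        if i > 0 and sequence.kinds[i - 1] == "blank":
            if not (sequence.final_truncated and i - 1 == sequence.n_events - 1):
                blank = float(sequence.durations[i - 1])
        if blank is None:
            seg_start.append(onset)
            seg_len.append(dur)
            continue
        resp_onset.append(onset)
        resp_s.append(np.log10(blank))
        pre = min(theta, dur)
        if pre > 0:
            seg_start.append(onset)
            seg_len.append(pre)
        post_start = onset + theta + window
        post_len = onset + dur - post_start
        if post_len > 0:
            seg_start.append(post_start)
            seg_len.append(post_len)

    seg_start_a = np.array(seg_start, dtype=float)
    seg_len_a = np.array(seg_len, dtype=float)
    counts_sp = rng.poisson(encoder.r0 * seg_len_a) if seg_len_a.size else np.array([], int)
    u_sp = rng.uniform(size=int(counts_sp.sum()))
    spont = np.repeat(seg_start_a, counts_sp) + u_sp * np.repeat(seg_len_a, counts_sp)

    resp_onset_a = np.array(resp_onset, dtype=float)
    resp_s_a = np.array(resp_s, dtype=float)
    if resp_s_a.size:
        mu_vec = np.asarray(encoder.mu(resp_s_a), dtype=float)
        mu_vec = mu_vec * _adaptation_gain(resp_onset_a, adapt_amplitude, adapt_tau)
        if encoder.noise == POISSON:
            counts_r = rng.poisson(mu_vec)
        else:
            sd = np.sqrt(np.asarray(encoder.sigma2(resp_s_a), dtype=float))
            counts_r = np.clip(np.rint(rng.normal(mu_vec, sd)), 0, None).astype(np.int64)
        u_r = rng.uniform(size=int(counts_r.sum()))
        resp = np.repeat(resp_onset_a + theta, counts_r) + u_r * window
    else:
        resp = np.array([], dtype=float)

    spikes = np.concatenate([spont, resp])
    spikes = spikes[(spikes >= 0) & (spikes <= total)]
    spikes = np.sort(spikes)
    # Break exact ties (probability ~0 in continuous time, but be safe).
    if spikes.size > 1:
        dup = np.diff(spikes) <= 0
        while np.any(dup):
            spikes[1:][dup] = spikes[:-1][dup] + 1e-9
            spikes = np.sort(spikes)
            dup = np.diff(spikes) <= 0
    return SpikeTrainRecording(
        spikes=spikes,
        sequence=sequence,
        distance_label=distance_label,
        dose_label=dose_label,
        neuron_id=neuron_id,
    )


def derive_min_whiff(sequence: StimulusSequence) -> float:
    """Shortest complete whiff duration in the sequence (inf if no whiffs).

    The truncated final event is ignored: its realized duration is an
    artifact of the recording end, not of the plume statistics.
    """
    mask = sequence.kinds == "whiff"
    if sequence.final_truncated and mask[-1]:
        mask = mask.copy()
        mask[-1] = False
    if not np.any(mask):
        return float("inf")
    return float(sequence.durations[mask].min())


def simulate_population(
    encoder: EncoderSpec,
    params: PlumeParams,
    n_neurons: int,
    duration_s: float,
    seed,
    whiff_cap="auto",
    dose_label: Optional[float] = None,
) -> list[SpikeTrainRecording]:
    """Simulate a homogeneous group of ORNs, one fresh sequence per neuron.

    Mirrors the experimental design in which each generated sequence was
    tested only once, on a single recorded ORN.  Child seeds are derived
    deterministically from the master seed.
    """
    if n_neurons < 1:
        raise ValueError(f"need n_neurons >= 1, got {n_neurons}")
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n_neurons) & 0x7FFFFFFF
    recordings = []
    for i in range(n_neurons):
        seq = generate_sequence(params, duration_s, int(states[2 * i]), whiff_cap=whiff_cap)
        rec = simulate_recording(
            encoder,
            seq,
            int(states[2 * i + 1]),
            neuron_id=f"syn-{params.d:g}m-{i:03d}",
            distance_label=params.d,
            dose_label=dose_label,
        )
        recordings.append(rec)
    return recordings
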