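"""End-to-end analysis pipeline over (distance, dose) groups.

Stages mirror the analysis order applied to the recordings: simulate (or
ingest) per-group spike trains, estimate the group latency, extract
latency-corrected responses, fit the duration-rate model, derive the Fisher
profile and the Jeffreys prior, and assemble the summary tables (mode
matching, matched-vs-mismatched average Fisher information, QQ deviations).
Fully deterministic given the config seed; every output file carries the
config hash.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import efficiency, encoding, latency, orn, plume
from .io import write_table

__all__ = [
    "DISTANCES",
    "DOSES",
    "GroupKey",
    "RunConfig",
    "GroupResult",
    "PipelineResult",
    "dose_scaled_saturating",
    "run_pipeline",
]

logger = logging.getLogger("ornplume")

#: Virtual distances (m) and pheromone doses (ng) of the stimulation protocol.
DISTANCES = (8.0, 16.0, 32.0, 64.0, 128.0)
DOSES = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1e0)


@dataclass(frozen=True)
class GroupKey:
    """A (virtual distance, pheromone dose) condition.

    The (128 m, 1 ng) combination is rejected: extremely long whiffs at that
    dose silence the neurons and the condition was never studied.
    """

    distance_m: float
    dose_ng: float

    def __post_init__(self) -> None:
        if float(self.distance_m) not in DISTANCES:
            raise ValueError(
                f"distance {self.distance_m} m not in protocol set {DISTANCES}"
            )
        if not any(math.isclose(float(self.dose_ng), d) for d in DOSES):
            raise ValueError(f"dose {self.dose_ng} ng not in protocol set {DOSES}")
        if float(self.distance_m) == 128.0 and math.isclose(float(self.dose_ng), 1.0):
            raise ValueError("the (128 m, 1 ng) condition was not studied")

    def label(self) -> str:
        return f"d{self.distance_m:g}m_dose{self.dose_ng:g}ng"


def dose_scaled_saturating(
    dose_ng: float,
    window: float = 0.150,
    r0: float = 5.0,
) -> orn.EncoderSpec:
    """Saturating encoder preset for a pheromone dose label.

    Higher doses raise the maximum rate and the slope of the duration-rate
    curve and shorten the latency (as observed across doses); the mapping is
    a simple monotone interpolation over the 10^-6..10^0 ng range and serves
    only to give dose labels distinct, plausible encoders.
    """
    g = (math.log10(dose_ng) + 6.0) / 6.0  # 0 at 1e-6 ng, 1 at 1 ng
    g = min(max(g, 0.0), 1.0)
    return orn.make_saturating_encoder(
        r_max=40.0 + 80.0 * g,
        s_half=0.45 - 0.25 * g,
        slope=2.0 + 3.0 * g,
        r0=r0,
        theta=0.032 - 0.012 * g,
        window=window,
    )


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    distances: tuple = (8.0, 16.0)
    doses: tuple = (1e-3,)
    n_neurons: int = 3
    duration_s: float = 500.0
    seed: int = 0
    encoder_kind: str = "saturating"  # or "jeffreys"
    encoder_params: dict = field(default_factory=dict)
    window: float = 0.150
    analysis_start: float = 100.0
    analysis_end: float = 500.0
    target_trace: float = 3.0
    grid_size: int = 201
    whiff_cap: object = "auto"
    tau_at_8m: Optional[float] = None  # if set, tau(d) = tau_at_8m * 8/d
    outdir: Optional[str] = None
    write_recordings: bool = False
    quiet: bool = False

    def group_keys(self) -> list[GroupKey]:
        return [GroupKey(d, dose) for d in self.distances for dose in self.doses]

    def plume_params(self, distance: float) -> plume.PlumeParams:
        override = None
        if self.tau_at_8m is not None:
            override = self.tau_at_8m * 8.0 / distance
        return plume.PlumeParams(d=distance, tau_override=override)

    def encoder_for(self, key: GroupKey) -> orn.EncoderSpec:
        bounds = plume.derive_timescales(self.plume_params(key.distance_m))
        if self.encoder_kind == "saturating":
            enc = dose_scaled_saturating(key.dose_ng, window=self.window)
            for name, value in self.encoder_params.items():
                setattr(enc, name, value)
            return enc
        if self.encoder_kind == "jeffreys":
            params = {"mu_min": 2.0, "c": 6.0, "r0": 5.0, "theta": 0.026}
            params.update(self.encoder_params)
            return orn.make_jeffreys_matched_encoder(
                bounds, window=self.window, **params
            )
        raise ValueError(f"unknown encoder kind {self.encoder_kind!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("distances", "doses"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the science-bearing configuration.

        Presentation-only fields (output directory, verbosity) are excluded,
        so reruns of the same analysis into different directories produce
        identical output files.
        """
        data = asdict(self)
        for skip in ("outdir", "quiet", "write_recordings"):
            data.pop(skip, None)
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class GroupResult:
    key: GroupKey
    n_samples: int
    latency_estimate: latency.LatencyEstimate
    fit: encoding.DurationRateFit
    profile: efficiency.FisherProfile
    prior: Optional[efficiency.JeffreysPrior]
    qq: Optional[efficiency.QQResult]
    bounds: plume.TimescaleBounds


@dataclass
class PipelineResult:
    config: RunConfig
    groups: dict
    modes: pd.DataFrame
    avg_fisher: dict  # dose -> AvgFisherComparison
    summary: pd.DataFrame


def _run_group(config: RunConfig, key: GroupKey, seed: int) -> GroupResult:
    params = config.plume_params(key.distance_m)
    bounds = plume.derive_timescales(params)
    encoder = config.encoder_for(key)
    recordings = orn.simulate_population(
        encoder,
        params,
        config.n_neurons,
        config.duration_s,
        seed,
        whiff_cap=config.whiff_cap,
        dose_label=key.dose_ng,
    )
    est = latency.estimate_latency(latency.collect_intervals(recordings))
    samples = encoding.extract_group_responses(
        recordings,
        est.theta_hat,
        window=config.window,
        analysis_start=config.analysis_start,
        analysis_end=config.analysis_end,
    )
    fit = encoding.fit_encoding_model(
        samples, target_trace=config.target_trace, grid_size=config.grid_size
    )
    profile = efficiency.fisher_profile(fit)
    try:
        prior = efficiency.jeffreys_prior(profile, bounds)
        qq = efficiency.qq_compare(prior, bounds)
    except ValueError:
        prior, qq = None, None
    return GroupResult(
        key=key,
        n_samples=len(samples),
        latency_estimate=est,
        fit=fit,
        profile=profile,
        prior=prior,
        qq=qq,
        bounds=bounds,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate -> latency -> fit -> Fisher -> Jeffreys -> report.

    Deterministic given ``config.seed``; per-group seeds are derived from it.
    Any stage error aborts with the stage name and group key.  When
    ``config.outdir`` is set, per-group model/profile/prior tables and the
    summary tables are written there with the config hash in their metadata.
    """
    if not config.quiet:
        logging.basicConfig(level=logging.INFO)
    keys = config.group_keys()  # validates all group keys up front
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(len(keys)) & 0x7FFFFFFF
    groups: dict = {}
    for key, seed in zip(keys, seeds):
        t0 = time.perf_counter()
        try:
            result = _run_group(config, key, int(seed))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for group {key.label()}: {exc}") from exc
        groups[key] = result
        if not config.quiet:
            logger.info(
                "group %s: n=%d, theta_hat=%.1f ms, trace=%.2f (%.1f s)",
                key.label(), result.n_samples,
                1e3 * result.latency_estimate.theta_hat,
                result.fit.trace, time.perf_counter() - t0,
            )

    modes = pd.DataFrame(
        [
            {
                "distance_m": key.distance_m,
                "dose_ng": key.dose_ng,
                "fi_mode": res.profile.mode,
                "dist_mode": plume.log_blank_mode(res.bounds),
                "n_samples": res.n_samples,
                "theta_hat_s": res.latency_estimate.theta_hat,
                "qq_max_dev": res.qq.max_abs_dev if res.qq else np.nan,
            }
            for key, res in groups.items()
        ]
    )
    avg_fisher = {}
    for dose in config.doses:
        profiles = {
            key.distance_m: res.profile
            for key, res in groups.items()
            if math.isclose(key.dose_ng, dose)
        }
        bounds_map = {
            key.distance_m: res.bounds
            for key, res in groups.items()
            if math.isclose(key.dose_ng, dose)
        }
        if len(profiles) >= 1:
            avg_fisher[dose] = efficiency.matched_vs_mismatched(profiles, bounds_map)

    summary = modes.copy()
    result = PipelineResult(
        config=config, groups=groups, modes=modes, avg_fisher=avg_fisher, summary=summary
    )
    if config.outdir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.config.config_hash}
    result.config.to_yaml(outdir / "config.yaml")
    write_table(result.summary, outdir / "summary.tsv", metadata=meta)
    write_table(result.modes, outdir / "modes.tsv", metadata=meta)
    for dose, comp in result.avg_fisher.items():
        table = comp.table.reset_index()
        write_table(table, outdir / f"avg_fisher_dose{dose:g}.tsv", metadata=meta)
    for key, res in result.groups.items():
        model = pd.DataFrame(
            {
                "s": res.fit.grid,
                "gamma": np.asarray(res.fit.gamma(res.fit.grid), dtype=float),
                "gamma_prime": np.asarray(res.fit.gamma_prime(res.fit.grid), dtype=float),
                "sigma2": np.asarray(res.fit.sigma2(res.fit.grid), dtype=float),
                "fisher": res.profile.F,
            }
        )
        write_table(
            model,
            outdir / f"model_{key.label()}.tsv",
            metadata={
                **meta,
                "lambda": res.fit.lam,
                "trace": res.fit.trace,
                "n": res.n_samples,
                "theta_hat_s": res.latency_estimate.theta_hat,
                "fi_mode": res.profile.mode,
            },
        )
        if res.prior is not None:
            prior_df = pd.DataFrame(
                {
                    "s": res.prior.grid,
                    "p_unit": res.prior.density,
                    "p_printed": res.prior.density_printed,
                }
            )
            write_table(
                prior_df,
                outdir / f"jeffreys_{key.label()}.tsv",
                metadata={**meta, "c": res.prior.c,
                          "alpha_median": res.prior.alpha_median},
            )
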