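# ornplume

Efficient-coding analysis of moth olfactory receptor neuron (ORN) responses
to the temporal statistics of turbulent pheromone plumes.

## The scientific problem

At a fixed point downwind of an odor source, turbulence chops the signal
into *whiffs* (odor present) and *blanks* (clean air).  Both durations
follow a truncated power law, `f(x) ∝ x^(-3/2)` on `[τ, T]`, where the
longest whiff `T_W = d/U` and blank `T_B = T_W (1/χ − 1)` grow with downwind
distance `d` (wind speed `U`, intermittency `χ`).  The distribution of blank
durations — the *stimulus-timescale distribution* — is therefore a signature
of the distance to the source.

The efficient coding hypothesis predicts that ORNs allocate their coding
resources to the most frequent stimulus timescales.  The package tests
this prediction end-to-end on synthetic spike trains with known ground
truth:

1. **Encoding model.** The spike count `r` in a 150 ms window after each
   latency-corrected whiff onset, as a function of `s = log10` of the
   preceding blank duration, is the *duration-rate relationship*.  Its mean
   `γ(s)` is fitted by a cubic smoothing spline (smoother trace ≈ 3) and its
   variance `σ²(s)` by robust segment IQRs, `(IQR/1.349)²`, smoothed with a
   tricube-weighted local line.
2. **Coding accuracy.** The Fisher information `F(s) ≈ γ′(s)² / σ²(s)`
   bounds the precision of an ideal decoder of `s`.
3. **Efficient-coding signatures.** (i) the mode of `F` aligns with the mode
   of the blank log-duration density `f(s)`; (ii) the stimulus-weighted
   average `⟨F⟩ = ∫ F(s) f(s) ds` is maximal under the matching plume
   statistics; (iii) the Jeffreys prior `p_J(s) ∝ √F(s)` — the
   mutual-information-optimal stimulus distribution when many noisy sensors
   converge on one decoder — reproduces `f(s)`.

A nonparametric latency estimator (comparing the empirical CDFs of the
spike intervals flanking whiff onsets) recovers the delivery delay that the
response windows must be corrected for.

## A worked example

```python
import ornplume as op

params = op.PlumeParams(d=8)                      # 8 m downwind, defaults U=1, χ=0.4
encoder = op.make_jeffreys_matched_encoder(       # Poisson encoder with √F ∝ f
    op.derive_timescales(params), mu_min=2.0, c=6.0, r0=5.0, theta=0.026)
recordings = op.simulate_population(encoder, params, 32, 500.0, seed=11)
latency = op.estimate_latency(op.collect_intervals(recordings))
samples = op.extract_group_responses(recordings, latency.theta_hat)
fit = op.fit_encoding_model(samples)
profile = op.fisher_profile(fit)
prior = op.jeffreys_prior(profile, op.derive_timescales(params))
qq = op.qq_compare(prior, op.derive_timescales(params))
print(len(samples), round(latency.theta_hat * 1e3, 1),
      round(profile.mode, 3), round(qq.max_abs_dev, 4))
```

prints

```
2034 26.2 0.0 0.0181
```

meaning: 2034 pooled responses; the injected 26 ms latency recovered to
26.2 ms; the coding-accuracy profile peaks at `s = 0.0` — exactly the mode
`log10 τ = 0` of the blank distribution at 8 m; and the quantiles of the
Jeffreys prior derived from the *estimated* Fisher profile deviate from the
true blank distribution by at most 0.018 log10 units, i.e. the synthetic
neuron is information-theoretically matched to its environment and the
pipeline detects it.

The `examples/` directory walks through each capability: plume statistics,
latency estimation, encoding/Fisher fits, the efficient-coding comparisons
across distances, and the file-based pipeline (`run_pipeline`).

## Layout

```
src/ornplume/
  plume.py        truncated power-law whiff/blank statistics, sequence generator
  orn.py          parametric encoders, synthetic spike-train simulation
  latency.py      nonparametric response-latency estimator
  encoding.py     response extraction, smoothing-spline mean, robust variance
  efficiency.py   Fisher profiles, ⟨F⟩, Jeffreys prior, QQ and mode comparisons
  io.py           plain-text sequence/recording/table formats
  pipeline.py     (distance, dose) group orchestration and reports
docs/methods.md   model assumptions, parameter choices, numerical details
examples/         one narrative script per capability
```
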