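# Methods

## Plume model

Whiff and blank durations at a virtual downwind distance `d` are drawn
independently from truncated power laws with density
`f(x) = x^(-3/2) / [2(1/√τ − 1/√T)]` on `[τ, T]`, with `T = T_W = d/U` for
whiffs and `T = T_B = T_W (1/χ − 1)` for blanks.  Defaults: `U = 1 m/s`,
`δU = 0.1 m/s`, `a = 0.1 m` (source size), `χ = 0.4`.  The shortest
timescale is computed exactly as `τ = a²d/[d·δU²]`; `d` cancels, so `τ = 1 s`
at every distance under the defaults.  Because a distance-independent `τ`
pins every blank-distribution mode to the same point (making mode-alignment
statistics across distances degenerate), `PlumeParams.tau_override` lets a
study impose a distance-dependent shortest timescale; the efficient-coding
study below uses `τ(d) = (8 m / d) · 1 s`, emulating a plume whose finest
filaments shrink with distance while leaving the printed formula untouched
as the default.

Closed forms used as oracles throughout the tests: CDF
`(1/√τ − 1/√x)/(1/√τ − 1/√T)`, quantile by direct inversion, mean `√(τT)`,
log10-duration density `10^(−s/2) ln10 / [2(1/√τ − 1/√T_B)]` (strictly
decreasing, mode at `log10 τ`), and the mean-based whiff-time fraction
`√T_W/(√T_W + √T_B)` ≈ 0.449 at `χ = 0.4` — the realized intermittency of
the alternating-renewal process, which differs from the nominal `χ` of the
generating model.

Sequences alternate blank/whiff starting with a blank, so every whiff onset
has a measurable preceding blank; durations are drawn by inverse transform,
one uniform per event in event order; the final event is truncated at the
total duration and flagged, and responses to a whiff whose preceding blank
is truncated are excluded downstream.  At 64 m and 128 m, whole sequences
containing any whiff longer than 30 s are rejected and regenerated (default
attempt limit 1000), mirroring the removal of extremely long puffs that
silence the neurons.  Durations are generated in continuous time and
serialized at 1 µs precision.

## Synthetic ORN encoders

An encoder maps `s = log10(preceding blank)` to the expected count `mu(s)`
in a `window = 150 ms` response window placed `theta` after the whiff onset.
Two families:

- **Saturating**: `mu(s) = window·[r0 + r_max/(1 + e^(−slope(s−s_half)))]` —
  the logistic shape of measured duration-rate curves.  Defaults used in
  recovery studies: `r_max = 100 Hz`, `s_half = 0.2`, `slope = 4`,
  `r0 = 5 Hz`, `theta = 26 ms`.
- **Jeffreys-matched**: `√mu(s) = √mu_min + (c/2)·CDF_log(s)` with Poisson
  noise, so that `F(s) = mu′²/mu = c²·f(s)²` exactly — the encoder a
  population optimized for mutual information should implement.  Study
  defaults `mu_min = 2` counts, `c = 6` (peak ≈ 170 Hz), chosen so counts
  stay in a regime where quartile-based variance estimation is meaningful
  while peak rates remain physiological.

Simulation places a Poisson(mu(s)) count uniformly in the response window
(the analysis uses only window counts, so within-window placement is free)
and runs homogeneous Poisson spontaneous activity at `r0` during blanks and
during whiff epochs outside the response window — including the pre-latency
gap `[onset, onset+theta)`, where physically the odor has not yet arrived;
this is what makes the latency estimator's interval statistics behave as in
real recordings.  An optional multiplicative gain `1 + A·e^(−t/τ_adapt)`
(default off) emulates the initial non-stationarity that motivates the
100–500 s analysis interval.  Pheromone dose enters only as a label mapped
to encoder presets (higher dose → higher `r_max` and slope, shorter
latency); there is no transduction model.

## Latency estimation

For each whiff onset, `w` = interval from the last spike inside the
preceding blank to the onset, `t` = interval from the onset to the first
subsequent spike; pairs lacking either spike are skipped and pairs pool
across the recordings of one (distance, dose) group.  With
`D(t) = F̂_T(t) − F̂_W(t)` (right-continuous empirical CDFs), the estimate is
the largest evaluation point `≤ t̃` with `D ≤ 0`, where `t̃` is the argmax
of `D` on `[0, max t]`.  `D` is evaluated only on the pooled sample points
plus 0 (step functions change nowhere else), and plateaus of the argmax
resolve to the smallest maximizer, so the admissible scan covers the whole
range below the first peak of `D`.  Below the true latency both intervals
are gaps of the same spontaneous process and `D ≈ 0`; the estimator's
accuracy therefore degrades at low spontaneous rates (sparse evaluation
points near the latency), visibly so below ~10 Hz.

## Encoding model fit

Responses are spike counts in `[onset+θ̂, onset+θ̂+150 ms)` for whiff onsets
within 100–500 s of the recording, against `s = log10(preceding blank)`,
pooled across the group.

**Mean.** `γ(s)` minimizes `Σ[rᵢ − γ(sᵢ)]² + λ∫γ″²`; `λ` is chosen by Brent
search on `log λ` so the exact smoother-matrix trace equals 3.0 ± 0.1
(effective degrees of freedom ≈ 3, the stiffness used on the real
recordings).  The trace is computed by the banded Reinsch identity
`df(λ) = m − λ·tr[(C + λΔW⁻¹Δᵀ)⁻¹ ΔW⁻¹Δᵀ]` on the distinct abscissas with
multiplicity weights `W`; abscissas are first merged at a resolution of
10⁻³ of the `s` range (the order of the 1 ms valve resolution), because the
penalty matrices contain `1/h³` of neighboring knot gaps and raw gaps of
10⁻⁶ make them numerically singular.  The fit itself is scipy's penalized
B-spline solver at the selected `λ`; the derivative `γ′` is the analytic
derivative of the fitted piecewise cubic.  The fit requires ≥ 10 samples
over ≥ 5 distinct `s` values.

**Variance.** Responses ordered by `s` are cut into maximally overlapping
segments of 10 (step 1); each yields `(IQR/1.349)²` with type-7 (linearly
interpolated) quartiles, located at the median `s` of its segment.  The raw
points are smoothed by local linear regression with tricube weights whose
kernel support spans 90% of the `s_center` range (half-width
`h = 0.45 × range`), floored at 10⁻⁶ counts² so Fisher ratios stay finite.
Known property: the type-7 sample IQR of 10 observations is inward-biased,
so `E[(IQR/1.349)²] ≈ 0.855 σ²`; the resulting ≈ +17% multiplicative bias
on `F` cancels in every shape-based comparison (modes, matched-vs-mismatched
ratios, normalized Jeffreys prior) but matters when `F` is compared
pointwise to a closed form — see Limitations.

## Coding accuracy and efficient-coding comparisons

`F(s) = γ′(s)²/σ²(s)` is evaluated on 201 equally spaced points of the
sample support; the mode is the grid argmax (smallest index on ties; the
grid quantizes the mode to ≤ 1% of the support, and values in the outer 20%
of the support are treated as unreliable).  The average accuracy
`⟨F⟩ = ∫F(s) f(s) ds` uses trapezoidal integration on a 2001-point refined
grid with `F` linearly interpolated — refined rather than the shared
201-point grid so the `F ≡ 1 ⇒ ⟨F⟩ = 1` identity holds to 10⁻⁶.  `⟨F⟩` is
evaluated for the matching distance and all shorter distances only (longer
distances have blank ranges on which `F` is undefined); up to 2% of blank
probability mass may fall outside the empirical profile support (the
sample extremes never reach the analytic bounds exactly) — more than that
raises an error naming the uncovered range.

The Jeffreys prior is reported in two conventions on
`[log10 τ, α(0.5)]` (`α(0.5)` = log10 of the median blank): the printed
constant `c = 2∫√F` under which the density integrates to 1/2, and a
unit-normalized density used for quantile comparison.  QQ comparison maps
levels 0.01…0.99 through the numeric inverse CDF of the prior and through
the closed-form conditional blank quantile `Q(p/2)`, and reports the
maximum absolute deviation in log10 units.  `p_J` is invariant under
`F → kF`, and when `F ∝ f²` the mode alignment survives any smooth monotone
rescaling of `s` (Fisher information transforms with the squared Jacobian,
densities with the Jacobian — `reparameterize` implements the check).

## The synthetic efficient-coding study

Study conditions (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`): five distances 8–128 m with `τ(d) = 8/d` s, two
Jeffreys-matched gain levels `c ∈ {4, 6}` standing in for dose variation,
≈ 2500 pooled responses per condition (the neuron count per condition is
scaled as `2500 × pair_length / 400 s`, where `pair_length =
√(τT_W) + √(τT_B)` is the expected whiff–blank cycle), 500 s recordings,
analysis interval 100–500 s, estimated (not injected) latency throughout.
Under these conditions the mode-alignment correlation is ≈ 1.0, the matched
diagonal maximizes every `⟨F⟩` row with a ≈ 1.5–2× margin per distance
step, and the QQ deviation stays below 0.02 log10 units.

With a distance-*independent* `τ`, the matched-diagonal property provably
reverses for `F ∝ f²` encoders: `⟨F⟩(m, d) ∝ A_d(1 − T_B(d)^{−3/2})` with
`A_d = ln10/[2(1/√τ − 1/√T_B(d))]` is decreasing in the applied distance
`d`, so narrower (shorter-distance) statistics, concentrated where a
monotonically decreasing `F` is largest, always win.  The distance-varying
`τ` separates the distributions' modes and restores the matched optimum;
this is the package's deliberate study-design choice.

## What the generator does and does not emulate

The synthetic data reproduce the statistical structure the analysis relies
on: power-law blank/whiff durations with distance-dependent ranges, a
saturating duration-rate response with Poisson (or Gaussian) count noise in
a fixed post-onset window, a fixed group-level latency, spontaneous
activity, and optional initial gain adaptation.  They do not emulate
concentration dynamics within whiffs, receptor/transduction kinetics,
heterogeneous populations, dose-dependent latency jitter within a group, or
recording artifacts.  Passing tests therefore demonstrate that the
estimators recover what they claim from data obeying the model's
assumptions — not that real recordings obey them.

## Numerical choices and degenerate inputs

- Latency: `D ≤ 0` uses a 10⁻¹² slack; ties in the argmax resolve to the
  smallest point; `n < 2` pairs is an error; estimates satisfy
  `0 ≤ θ̂ ≤ t̃ ≤ max t` by construction.
- Spline: trace targets outside `(2, m)` are rejected (the penalty's null
  space of straight lines bounds the trace below by 2); exact duplicate
  ties in `s` are weight-merged before fitting.
- Variance smoothing: a degenerate single-cluster input returns a constant;
  queries where all tricube weights vanish raise an error.
- All simulation randomness flows through numpy Generators seeded from a
  single integer; population and pipeline stages derive child seeds via
  `SeedSequence` (masked below 2³¹), and the random stream of a recording
  is consumed in a fixed order, so every result is reproducible bit for bit.
- Pipeline outputs are plain text with `#` metadata including a hash of the
  science-bearing configuration; reruns are byte-identical.

## Known limitations

- Pointwise recovery of `F` against a closed form is limited to roughly
  ±30–50% near the edges of the central support at n ≈ 2000: the trace-3
  spline's derivative carries up to ~18% deterministic smoothing bias
  (measured noise-free), and the segment-of-10 IQR variance carries the
  0.855 multiplicative bias above.  Both are properties of the estimation
  procedure itself, not of its implementation; all shape- and
  normalization-based conclusions are unaffected.
- The latency estimator needs spontaneous activity; at `r0 ≲ 10 Hz` its
  error grows to tens of ms (it remains unbiased in the median at 20 Hz,
  ~500 onsets: median error ≈ 1.4 ms).
- `⟨F⟩` comparisons require the applied distance's blank range to be
  covered by the profile; only shorter-or-equal distances are admissible.
- The spike+valve file reader reconstructs the stimulus from valve events
  and flags its trailing blank as truncated; recordings ingested this way
  need no paired stimulus file but inherit the valve times' resolution.
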