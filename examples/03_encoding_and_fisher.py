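"""Duration-rate encoding model and Fisher-information profile.

Pools ~2000 synthetic responses from a saturating Poisson encoder, fits the
mean curve by a cubic smoothing spline (smoother trace ~ 3) and the variance
by robust segment IQRs with tricube local-linear smoothing, and compares the
resulting coding-accuracy profile F(s) = gamma'(s)^2 / sigma^2(s) with the
encoder's closed form.
"""

import numpy as np

import ornplume as op

params = op.PlumeParams(d=8)
encoder = op.make_saturating_encoder(r_max=100, s_half=0.2, slope=4, r0=5.0,
                                     theta=0.026)
recordings = op.simulate_population(encoder, params, 32, 500.0, seed=11)
latency = op.estimate_latency(op.collect_intervals(recordings))
samples = op.extract_group_responses(recordings, latency.theta_hat)
fit = op.fit_encoding_model(samples)
profile = op.fisher_profile(fit)

print(f"pooled responses: n = {len(samples)}")
print(f"spline penalty lambda = {fit.lam:.3g}, smoother trace = {fit.trace:.2f}")
print(f"Fisher mode (most accurately decoded blank log-duration): "
      f"{profile.mode:+.3f} log10 s")

analytic = op.analytic_fisher(encoder, profile.grid)
lo, hi = fit.support
central = (profile.grid > lo + 0.2 * (hi - lo)) & (profile.grid < hi - 0.2 * (hi - lo))
rel = np.abs(profile.F[central] - analytic[central]) / analytic[central]
print(f"median relative deviation from the closed-form F on the central 60% "
      f"of the support: {np.median(rel) * 100:.1f}%")
print("Large deviations concentrate at the support edges, where data are "
      "sparse and the profile is flagged unreliable.")
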