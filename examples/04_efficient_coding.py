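"""Efficient-coding signatures across virtual distances.

Builds a Jeffreys-matched encoder per distance (Fisher information
proportional to the squared blank-duration density), runs the full
estimation pipeline, and reproduces the three signatures: Fisher modes align
with the most frequent blank durations, the stimulus-weighted average Fisher
information peaks for the matching distance, and the Jeffreys prior derived
from the estimated profile reproduces the true blank distribution.
"""

import math

import numpy as np

import ornplume as op

DISTANCES = (8.0, 16.0, 32.0, 64.0, 128.0)

profiles, bounds_map, mode_pairs = {}, {}, []
for i, d in enumerate(DISTANCES):
    # shortest-timescale override tau(d) = 8/d spreads the distribution
    # modes across distances, as in a plume whose finest filaments shrink
    # with downwind distance
    params = op.PlumeParams(d=d, tau_override=8.0 / d)
    b = op.derive_timescales(params)
    bounds_map[d] = b
    encoder = op.make_jeffreys_matched_encoder(b, mu_min=2.0, c=6.0, r0=5.0,
                                               theta=0.026)
    pair_len = math.sqrt(b.tau * b.T_W) + math.sqrt(b.tau * b.T_B)
    n_neurons = max(2, math.ceil(2000 * pair_len / 400.0))
    recordings = op.simulate_population(encoder, params, n_neurons, 500.0,
                                        seed=100 + i)
    latency = op.estimate_latency(op.collect_intervals(recordings))
    samples = op.extract_group_responses(recordings, latency.theta_hat)
    fit = op.fit_encoding_model(samples)
    profiles[d] = op.fisher_profile(fit)
    mode_pairs.append((profiles[d].mode, op.log_blank_mode(b)))
    print(f"d = {d:5.0f} m: n = {len(samples):5d}, Fisher mode "
          f"{profiles[d].mode:+.3f}, blank-density mode "
          f"{op.log_blank_mode(b):+.3f} (log10 s)")

print(f"\nmode correlation R = {op.mode_correlation(mode_pairs):.3f} "
      "(1.0 = perfect alignment of coding accuracy with stimulus statistics)")

comp = op.matched_vs_mismatched(profiles, bounds_map)
print("\naverage Fisher information <F> (rows: encoder distance, "
      "cols: applied plume statistics):")
print(comp.table.round(1).to_string())
print("matched diagonal is the row maximum:", comp.matched_best.all())

b8 = bounds_map[8.0]
prior = op.jeffreys_prior(profiles[8.0], b8)
qq = op.qq_compare(prior, b8)
print(f"\nJeffreys prior vs true blank distribution at 8 m: "
      f"max QQ deviation {qq.max_abs_dev:.4f} log10 units "
      "(small values mean the encoder is information-theoretically matched "
      "to its environment)")
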