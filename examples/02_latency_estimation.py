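"""Nonparametric response-latency estimation.

Simulates a group of ORN recordings with a known 26 ms delivery latency and
recovers it by comparing the empirical CDFs of the spike intervals flanking
each whiff onset: the estimate is the last point before the first peak of
F_T - F_W at which the difference is still non-positive.
"""

import ornplume as op

params = op.PlumeParams(d=8)
encoder = op.make_saturating_encoder(
    r_max=100, s_half=0.2, slope=4, r0=20.0, theta=0.026
)
recordings = op.simulate_population(encoder, params, 4, 800.0, seed=7)
intervals = op.collect_intervals(recordings)
estimate = op.estimate_latency(intervals)

print(f"interval pairs pooled across {len(recordings)} recordings: n = {intervals.n}")
print(f"injected latency: 26.0 ms")
print(f"estimated latency: {estimate.theta_hat * 1e3:.1f} ms "
      f"(argmax point t~ = {estimate.t_tilde * 1e3:.1f} ms)")
print("The estimate feeds the response-window placement of every later stage;"
      " a few ms of error shifts the window slightly but scales all responses"
      " alike.")
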