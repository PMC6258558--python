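"""Response extraction, smoothing-spline mean fit and robust variance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import make_smoothing_spline

import ornplume as op
from ornplume.encoding import _SmootherTrace, _merge_duplicates
from conftest import make_periodic_sequence


def samples_frame(s, r):
    return pd.DataFrame({"s": s, "r": r, "onset": np.arange(len(s), dtype=float),
                         "recording_id": "t"})


class TestExtractResponses:
    def test_window_count_and_latency_correction(self):
        seq = make_periodic_sequence(200.0, 100.0, n_pairs=2)  # whiff onset at 200.0
        spikes = np.array([200.10, 200.20, 200.24, 200.26])
        rec = op.SpikeTrainRecording(spikes=spikes, sequence=seq)
        out = op.extract_responses(rec, theta=0.026, analysis_start=100,
                                   analysis_end=500)
        row = out[np.isclose(out.onset, 200.0)].iloc[0]
        assert row.r == 1  # only 200.10 falls in [200.026, 200.176)
        assert row.s == pytest.approx(math.log10(200.0))

    def test_onsets_outside_analysis_interval_excluded(self):
        seq = make_periodic_sequence(25.0, 25.0, n_pairs=12)  # onsets at 25, 75, ...
        rec = op.SpikeTrainRecording(spikes=np.array([]), sequence=seq)
        out = op.extract_responses(rec, theta=0.0, analysis_start=100,
                                   analysis_end=500)
        assert out.onset.min() >= 100.0 and out.onset.max() <= 500.0
        assert 25.0 not in set(out.onset) and 75.0 not in set(out.onset)

    def test_log10_of_preceding_blank(self, params8, logistic_encoder):
        seq = op.generate_sequence(params8, 400.0, seed=13)
        rec = op.simulate_recording(logistic_encoder, seq, seed=14)
        out = op.extract_responses(rec, theta=0.026)
        blanks = {round(o, 6): b for o, _d, b in seq.whiff_events() if b is not None}
        for _, row in out.iterrows():
            assert row.s == pytest.approx(math.log10(blanks[round(row.onset, 6)]))

    def test_analysis_interval_outside_recording_warns_empty(self):
        seq = make_periodic_sequence(10.0, 10.0, n_pairs=2)  # 40 s total
        rec = op.SpikeTrainRecording(spikes=np.array([]), sequence=seq)
        with pytest.warns(UserWarning):
            out = op.extract_responses(rec, theta=0.0, analysis_start=100)
        assert len(out) == 0


class TestPoolSamples:
    def test_concatenation_sorting_and_multiset(self):
        a = samples_frame([0.5, 0.1, 0.9], [1, 2, 3])
        b = samples_frame([0.3, 0.7], [4, 5])
        pooled = op.pool_samples([a, b])
        assert len(pooled) == 5
        assert np.all(np.diff(pooled.s) >= 0)
        assert sorted(zip(pooled.s, pooled.r)) == sorted(
            list(zip(a.s, a.r)) + list(zip(b.s, b.r))
        )


class TestSplineFit:
    def test_line_data_recovered_exactly(self):
        s = np.linspace(0, 1, 40)
        fit = op.fit_duration_rate(samples_frame(s, 2 * s + 1))
        g = np.linspace(0.05, 0.95, 17)
        assert np.allclose(fit.gamma(g), 2 * g + 1, atol=1e-8)
        assert np.allclose(fit.gamma_prime(g), 2.0, atol=1e-7)

    def test_trace_limits(self):
        x = np.linspace(0, 1, 30)
        tracer = _SmootherTrace(x, np.ones_like(x))
        assert tracer.df(1e12) == pytest.approx(2.0, abs=1e-3)  # line null space
        assert tracer.df(1e-14) == pytest.approx(30.0, abs=1e-3)
        lams = 10.0 ** np.linspace(-8, 4, 25)
        dfs = [tracer.df(l) for l in lams]
        assert np.all(np.diff(dfs) < 1e-9)  # monotone non-increasing in lambda

    def test_trace_against_smoother_column_probe(self):
        # independent oracle: sum of d(fitted_i)/d(y_i) probed through scipy
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 1, 30))
        x[4] = x[3]  # duplicate abscissa
        lam = 1e-3
        xu, inv, cnt = np.unique(x, return_inverse=True, return_counts=True)
        w = cnt.astype(float)
        probe = 0.0
        for j in range(len(x)):
            e = np.zeros(len(x)); e[j] = 1.0
            yu = np.bincount(inv, weights=e) / cnt
            probe += make_smoothing_spline(xu, yu, w=w, lam=lam)(x[j])
        assert _SmootherTrace(xu, w).df(lam) == pytest.approx(probe, abs=1e-8)

    def test_trace_hits_target(self, logistic_fit):
        assert abs(logistic_fit.trace - 3.0) <= 0.1

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            op.fit_duration_rate(samples_frame([0.1] * 12, range(12)))
        with pytest.raises(ValueError):
            op.fit_duration_rate(samples_frame([0.1, 0.2, 0.3], [1, 2, 3]))

    def test_mean_curve_recovery(self, logistic_fit, logistic_encoder):
        lo, hi = logistic_fit.support
        R = hi - lo
        g = np.linspace(lo + 0.2 * R, hi - 0.2 * R, 101)
        mu = logistic_encoder.mu(g)
        rng_mu = np.ptp(logistic_encoder.mu(np.linspace(lo, hi, 201)))
        assert np.max(np.abs(np.asarray(logistic_fit.gamma(g)) - mu)) <= 0.05 * rng_mu


class TestRobustVariance:
    def test_window_iqr_value(self):
        s = np.linspace(0, 1, 10)
        r = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        pts = op.robust_variance_points(samples_frame(s, r))
        assert len(pts) == 1
        # type-7 quartiles give IQR = 2 -> (2/1.349)^2
        assert pts.variance_raw[0] == pytest.approx((2 / 1.349) ** 2, abs=1e-9)
        assert pts.variance_raw[0] == pytest.approx(2.198042, abs=1e-5)
        assert pts.s_center[0] == pytest.approx(np.median(s))

    def test_constant_counts_give_zero_variance(self):
        pts = op.robust_variance_points(samples_frame(np.linspace(0, 1, 15), [3] * 15))
        assert np.allclose(pts.variance_raw, 0.0)

    def test_window_count(self):
        pts = op.robust_variance_points(samples_frame(np.linspace(0, 1, 37),
                                                      np.arange(37)))
        assert len(pts) == 37 - 10 + 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            op.robust_variance_points(samples_frame([0.1, 0.2], [1, 2]))


class TestSmoothVariance:
    def test_exact_line_reproduced(self):
        sc = np.linspace(0, 2, 25)
        pts = pd.DataFrame({"s_center": sc, "variance_raw": 3 * sc + 0.5})
        sigma2 = op.smooth_variance(pts)
        q = np.linspace(0.1, 1.9, 9)
        assert np.allclose(sigma2(q), 3 * q + 0.5, atol=1e-9)

    def test_identical_cluster_gives_constant(self):
        pts = pd.DataFrame({"s_center": [0.4] * 6, "variance_raw": [2.0] * 6})
        sigma2 = op.smooth_variance(pts)
        assert sigma2(0.4) == pytest.approx(2.0)
        assert sigma2(1.0) == pytest.approx(2.0)

    def test_floor_keeps_variance_positive(self):
        pts = pd.DataFrame({"s_center": np.linspace(0, 1, 12),
                            "variance_raw": np.zeros(12)})
        sigma2 = op.smooth_variance(pts)
        assert np.all(np.asarray(sigma2(np.linspace(0, 1, 33))) > 0)

    def test_variance_recovery_against_poisson_mean(self, logistic_fit,
                                                    logistic_encoder):
        lo, hi = logistic_fit.support
        R = hi - lo
        g = np.linspace(lo + 0.2 * R, hi - 0.2 * R, 101)
        mu = logistic_encoder.mu(g)
        rel = np.abs(np.asarray(logistic_fit.sigma2(g)) - mu) / mu
        assert rel.max() <= 0.25


class TestMergeDuplicates:
    def test_near_duplicates_pooled_with_weights(self):
        s = np.array([0.0, 1e-9, 0.5, 1.0])
        r = np.array([1.0, 3.0, 5.0, 7.0])
        xu, y, w = _merge_duplicates(s, r)
        assert len(xu) == 3
        assert y[0] == pytest.approx(2.0)
        assert w.tolist() == [2.0, 1.0, 1.0]
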