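"""Fisher profiles, average decoding accuracy and Jeffreys-prior comparisons."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import ornplume as op
from ornplume.encoding import DurationRateFit

DISTANCES = (8.0, 16.0, 32.0, 64.0, 128.0)


def fit_from_functions(gamma, gamma_prime, sigma2, support=(0.0, 1.0)):
    grid = np.linspace(support[0], support[1], 201)
    return DurationRateFit(
        gamma=gamma, gamma_prime=gamma_prime, sigma2=sigma2,
        support=support, lam=1.0, trace=3.0, grid=grid, n_samples=0,
    )


def const(v):
    return lambda s: np.full_like(np.asarray(s, dtype=float), v)


class TestFisherProfile:
    def test_zero_slope_gives_zero_information(self):
        fit = fit_from_functions(const(3.0), const(0.0), const(4.0))
        assert np.allclose(op.fisher_profile(fit).F, 0.0)

    def test_linear_mean_constant_variance(self):
        fit = fit_from_functions(lambda s: 2 * s + 1, const(2.0), const(4.0))
        prof = op.fisher_profile(fit)
        assert np.allclose(prof.F, 1.0)

    def test_mode_is_smallest_grid_argmax(self):
        fit = fit_from_functions(const(0.0), const(1.0), const(1.0))
        prof = op.fisher_profile(fit)  # constant F: tie -> smallest s
        assert prof.mode == prof.grid[0]

    def test_nonpositive_variance_rejected(self):
        fit = fit_from_functions(const(0.0), const(1.0), const(0.0))
        with pytest.raises(ValueError):
            op.fisher_profile(fit)


class TestNormalize:
    def test_maximum_becomes_one_and_idempotent(self):
        prof = op.profile_from_function(lambda s: 3 + np.sin(s), (0.0, 2.0))
        normed = op.normalize_profile(prof)
        assert normed.F.max() == pytest.approx(1.0)
        assert normed.mode == prof.mode
        again = op.normalize_profile(normed)
        assert np.allclose(again.F, normed.F)

    def test_constant_profile_becomes_all_ones(self):
        prof = op.profile_from_function(const(5.0), (0.0, 1.0))
        assert np.allclose(op.normalize_profile(prof).F, 1.0)

    def test_zero_profile_rejected(self):
        prof = op.profile_from_function(const(0.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            op.normalize_profile(prof)


class TestAverageFisher:
    @pytest.mark.parametrize("d", DISTANCES)
    def test_unit_profile_averages_to_one(self, d):
        b = op.derive_timescales(op.PlumeParams(d=d))
        prof = op.profile_from_function(
            const(1.0), (math.log10(b.tau), math.log10(b.T_B))
        )
        assert op.average_fisher(prof, b) == pytest.approx(1.0, abs=1e-6)

    def test_zero_profile_averages_to_zero(self, bounds8):
        prof = op.profile_from_function(const(0.0), (0.0, math.log10(12)))
        assert op.average_fisher(prof, bounds8) == 0.0

    def test_density_profile_against_quadrature_oracle(self, bounds8):
        prof = op.profile_from_function(
            lambda s: op.log_blank_density(s, bounds8), (0.0, math.log10(12))
        )
        oracle, _ = quad(
            lambda s: op.log_blank_density(s, bounds8) ** 2, 0, math.log10(12)
        )
        assert op.average_fisher(prof, bounds8) == pytest.approx(oracle, rel=1e-4)

    def test_bounded_by_profile_extremes(self, bounds8):
        rng = np.random.default_rng(2)
        for _ in range(5):
            vals = rng.uniform(0.5, 4.0, size=201)
            grid = np.linspace(0.0, math.log10(12), 201)
            prof = op.FisherProfile(grid=grid, F=vals, mode=grid[int(np.argmax(vals))],
                                    support=(0.0, math.log10(12)))
            av = op.average_fisher(prof, bounds8)
            assert vals.min() - 1e-9 <= av <= vals.max() + 1e-9

    def test_uncovered_blank_range_rejected_with_named_range(self, bounds8):
        b16 = op.derive_timescales(op.PlumeParams(d=16))
        prof = op.profile_from_function(const(1.0), (0.0, math.log10(12)))
        with pytest.raises(ValueError, match="uncovered"):
            op.average_fisher(prof, b16)  # blanks up to 24 s, profile stops at 12 s


class TestMatchedVsMismatched:
    def test_single_distance_trivially_matched(self, bounds8):
        prof = op.profile_from_function(const(2.0), (0.0, math.log10(12)))
        comp = op.matched_vs_mismatched({8.0: prof}, {8.0: bounds8})
        assert comp.table.shape == (1, 1)
        assert comp.matched_best[8.0]

    def test_table_is_lower_triangular(self):
        profiles, bounds = {}, {}
        for d in (8.0, 16.0, 32.0):
            b = op.derive_timescales(op.PlumeParams(d=d))
            bounds[d] = b
            profiles[d] = op.profile_from_function(
                const(1.0), (math.log10(b.tau), math.log10(b.T_B))
            )
        comp = op.matched_vs_mismatched(profiles, bounds)
        arr = comp.table.to_numpy()
        assert np.all(np.isnan(arr[np.triu_indices(3, k=1)]))
        assert np.all(np.isfinite(arr[np.tril_indices(3)]))


class TestMedianLogBlank:
    def test_closed_form_value(self, bounds8):
        assert op.median_log_blank(bounds8) == pytest.approx(0.381773, abs=1e-6)

    def test_monotone_in_upper_bound(self):
        meds = [
            op.median_log_blank(op.derive_timescales(op.PlumeParams(d=d)))
            for d in (8, 16, 32, 64, 128)
        ]
        assert np.all(np.diff(meds) > 0)

    def test_near_degenerate_upper_bound(self):
        b = op.TimescaleBounds(tau=1.0, T_W=8.0, T_B=1.0 + 1e-9)
        assert op.median_log_blank(b) == pytest.approx(0.0, abs=1e-9)


class TestJeffreysPrior:
    def test_constant_profile_gives_uniform_unit_density(self, bounds8):
        prof = op.profile_from_function(const(7.0), (0.0, math.log10(12)))
        prior = op.jeffreys_prior(prof, bounds8)
        alpha = op.median_log_blank(bounds8)
        assert np.allclose(prior.density, 1.0 / alpha)
        assert prior.density[0] == pytest.approx(2.61936, abs=1e-4)

    def test_printed_constant_integrates_to_half(self, bounds8):
        prof = op.profile_from_function(const(7.0), (0.0, math.log10(12)))
        prior = op.jeffreys_prior(prof, bounds8)
        assert np.trapezoid(prior.density_printed, prior.grid) == pytest.approx(0.5)

    def test_invariant_under_positive_rescaling(self, bounds8):
        base = op.profile_from_function(
            lambda s: op.log_blank_density(s, bounds8) ** 2, (0.0, math.log10(12))
        )
        scaled = op.profile_from_function(
            lambda s: 9.4 * op.log_blank_density(s, bounds8) ** 2,
            (0.0, math.log10(12)),
        )
        a = op.jeffreys_prior(base, bounds8)
        c = op.jeffreys_prior(scaled, bounds8)
        assert np.allclose(a.density, c.density)

    def test_square_of_density_recovers_density(self, bounds8):
        prof = op.profile_from_function(
            lambda s: 2.5 * op.log_blank_density(s, bounds8) ** 2,
            (0.0, math.log10(12)),
        )
        prior = op.jeffreys_prior(prof, bounds8)
        f = op.log_blank_density(prior.grid, bounds8)
        expected = f / np.trapezoid(f, prior.grid)
        assert np.max(np.abs(prior.density - expected)) < 1e-4 * expected.max()

    def test_vanishing_information_rejected(self, bounds8):
        prof = op.profile_from_function(const(0.0), (0.0, math.log10(12)))
        with pytest.raises(ValueError):
            op.jeffreys_prior(prof, bounds8)


class TestQQCompare:
    def test_matching_distributions_lie_on_diagonal(self, bounds8):
        prof = op.profile_from_function(
            lambda s: op.log_blank_density(s, bounds8) ** 2, (0.0, math.log10(12))
        )
        qq = op.qq_compare(op.jeffreys_prior(prof, bounds8), bounds8)
        assert qq.max_abs_dev < 1e-3

    def test_uniform_prior_deviates_from_decreasing_density(self, bounds8):
        prof = op.profile_from_function(const(1.0), (0.0, math.log10(12)))
        qq = op.qq_compare(op.jeffreys_prior(prof, bounds8), bounds8)
        assert qq.max_abs_dev > 0.01
        # uniform prior puts more mass on long blanks than the real density
        assert np.all(qq.predicted[1:-1] >= qq.real[1:-1])


class TestModeCorrelation:
    def test_identity_line(self):
        pairs = [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0), (1.5, 1.5)]
        assert op.mode_correlation(pairs) == pytest.approx(1.0)

    def test_anti_ordered(self):
        pairs = [(0.0, 2.0), (1.0, 1.0), (2.0, 0.0)]
        assert op.mode_correlation(pairs) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            op.mode_correlation([(1.0, 0.0), (1.0, 1.0), (1.0, 2.0)])


class TestReparameterization:
    def test_mode_match_preserved_under_rescaling(self, bounds8):
        # F proportional to f^2: modes coincide in any parameterization
        grid = np.linspace(0.0, math.log10(12), 801)
        f = op.log_blank_density(grid, bounds8)
        F = 4.0 * f**2

        def phi(s):
            return np.expm1(1.5 * np.asarray(s))

        def phi_prime(s):
            return 1.5 * np.exp(1.5 * np.asarray(s))

        new_grid, F_new, f_new = op.reparameterize(grid, F, f, phi, phi_prime)
        assert np.all(np.diff(new_grid) > 0)
        assert new_grid[np.argmax(F_new)] == new_grid[np.argmax(f_new)]

    def test_decreasing_rescaling_rejected(self):
        grid = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            op.reparameterize(grid, grid, grid, lambda s: -s,
                              lambda s: -np.ones_like(s))
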