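"""Error-model building blocks: deviations, rankits, initialization,
the binned target, its analytic gradient, and refinement behavior."""

import numpy as np
import pytest
from scipy import optimize as sciopt
from scipy import stats

from sxmerge.data_model import ReflectionGroup, ValidationError
from sxmerge.ev11 import (
    ErrorModelParams,
    bin_measurements,
    deviations_for_plot,
    fit_npp_line,
    initialize_params,
    leave_one_out_mean,
    normal_probability_plot,
    normalized_deviation,
    prepare_groups,
    rankits,
    refine_error_model,
    sigma_ev11,
    target_function,
    target_gradient,
)


def _group(i, s=None, hkl=(1, 0, 0)):
    i = np.asarray(i, dtype=float)
    s = np.ones_like(i) if s is None else np.asarray(s, dtype=float)
    return ReflectionGroup(hkl=hkl, intensities=i, sigmas=s)


def gaussian_groups(rng, n_groups, n_per, sigma=3.0, mean_range=(50.0, 5000.0)):
    """Groups with exactly Gaussian scatter of known sigma, true means spread
    widely so that intensity binning reflects signal rather than noise."""
    means = rng.uniform(*mean_range, n_groups)
    return [
        _group(rng.normal(means[g], sigma, n_per), np.full(n_per, sigma),
               (g, 0, 0))
        for g in range(n_groups)
    ]


class TestLeaveOneOut:
    def test_two_measurements(self):
        assert leave_one_out_mean(_group([4, 6]), 0) == 6.0
        assert leave_one_out_mean(_group([4, 6]), 1) == 4.0

    def test_single_measurement_defined_as_zero(self):
        assert leave_one_out_mean(_group([7]), 0) == 0.0

    def test_algebraic_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            g = _group(rng.normal(0, 10, n))
            j = int(rng.integers(0, n))
            expected = (n * g.intensities.mean() - g.intensities[j]) / (n - 1)
            assert leave_one_out_mean(g, j) == pytest.approx(expected, rel=1e-12)


class TestNormalizedDeviation:
    def test_single_measurement_is_zero(self):
        assert normalized_deviation(_group([7]), 0, sigma=1.0) == 0.0

    def test_zero_numerator(self):
        g = _group([10, 10])
        assert normalized_deviation(g, 0, sigma=5.0) == 0.0
        assert normalized_deviation(g, 1, sigma=5.0) == 0.0

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValidationError):
            normalized_deviation(_group([1, 2]), 0, sigma=0.0)

    def test_monte_carlo_unit_variance(self, rng):
        """With the true sigma supplied, the (n-1)/n prefactor makes the
        deviations unit-variance regardless of group size."""
        devs = []
        for n_per in (2, 3, 6):
            groups = gaussian_groups(rng, 20000 // n_per, n_per)
            devs.append(deviations_for_plot(groups))
        d = np.concatenate(devs)
        se = 1.0 / np.sqrt(2 * (len(d) - 1))  # SE of an SD estimate
        assert np.std(d) == pytest.approx(1.0, abs=3 * se)


class TestRankits:
    def test_m5_rankits(self):
        z = rankits(5)
        # the median is exact; the 2nd/4th rankits approximate the normal
        # quartiles (the a = 3/8 plotting position puts them at +-Phi^-1(0.31))
        assert z[2] == pytest.approx(0.0, abs=1e-14)
        assert z[1] == pytest.approx(stats.norm.ppf((2 - 0.375) / 5.25), rel=1e-12)
        assert z[1] == pytest.approx(stats.norm.ppf(0.25), abs=0.2)
        assert z[3] == pytest.approx(stats.norm.ppf(0.75), abs=0.2)

    def test_single_observation(self):
        assert rankits(1)[0] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("m", range(1, 51))
    def test_matches_numerical_inverse_cdf(self, m):
        """Oracle: invert the normal CDF numerically with a root finder."""
        a = 0.375 if m <= 10 else 0.5
        z = rankits(m)
        for i in (1, (m + 1) // 2, m):
            q = (i - a) / (m + 1 - 2 * a)
            root = sciopt.brentq(lambda x: stats.norm.cdf(x) - q, -10, 10,
                                 xtol=1e-12)
            assert z[i - 1] == pytest.approx(root, abs=1e-10)

    def test_antisymmetry(self):
        for m in (2, 7, 11, 40):
            z = rankits(m)
            np.testing.assert_allclose(z + z[::-1], 0.0, atol=1e-12)


class TestNormalProbabilityPlot:
    def test_perfectly_normal_deviations(self):
        z = rankits(1001)
        slope, offset = fit_npp_line(z, z)
        assert slope == pytest.approx(1.0, rel=1e-12)
        assert offset == pytest.approx(0.0, abs=1e-12)

    def test_affine_deviations(self):
        z = rankits(501)
        slope, offset = fit_npp_line(2.0 * z + 0.3, z)
        assert slope == pytest.approx(2.0, rel=1e-10)
        assert offset == pytest.approx(0.3, rel=1e-10)

    def test_sampled_gaussian_recovers_scale(self, rng):
        d = rng.normal(0.0, 1.5, 100_000)
        plot = normal_probability_plot(d)
        assert plot.slope == pytest.approx(1.5, abs=0.05)
        assert plot.offset == pytest.approx(0.0, abs=0.05)

    def test_too_few_central_points(self):
        with pytest.raises(ValidationError, match="fit range"):
            fit_npp_line(np.array([-3.0, 3.0]), np.array([-3.0, 3.0]))


class TestInitializeParams:
    @pytest.mark.parametrize(
        "slope, offset, expected",
        [
            (1.0, 0.0, (1.0, 0.0, 0.0)),
            # printed initializations for the 5000-image subsets: the s_B
            # value equals the square root of the offset-derived s_add
            (1.44, 0.45, (1.44, 0.45 ** 0.5, 0.45)),
            (7.47, 0.52, (7.47, 0.52 ** 0.5, 0.52)),
        ],
    )
    def test_slope_offset_mapping(self, slope, offset, expected):
        p = initialize_params(slope, offset)
        assert (p.s_fac, p.s_B, p.s_add) == pytest.approx(expected, rel=1e-12)
        if offset == 0.45:
            assert p.s_B == pytest.approx(0.6708, abs=5e-5)

    def test_negative_offset_clamped(self):
        p = initialize_params(1.2, -0.3)
        assert p.s_add == 0.0 and p.s_B == 0.0


class TestSigmaEv11:
    def test_identity_params(self):
        assert sigma_ev11(3.0, 100.0, ErrorModelParams(1.0, 0.0, 0.0)) == 3.0

    def test_hand_evaluation(self):
        # 2 * sqrt(3^2 + 1*16 + (0.5*16)^2) = 2 * sqrt(89)
        out = sigma_ev11(3.0, 16.0, ErrorModelParams(2.0, 1.0, 0.5))
        assert out == pytest.approx(2.0 * np.sqrt(89.0), rel=1e-12)

    def test_monotone_in_each_parameter(self):
        base = sigma_ev11(3.0, 16.0, ErrorModelParams(1.5, 0.5, 0.2))
        assert sigma_ev11(3.0, 16.0, ErrorModelParams(1.6, 0.5, 0.2)) > base
        assert sigma_ev11(3.0, 16.0, ErrorModelParams(1.5, 0.6, 0.2)) > base
        assert sigma_ev11(3.0, 16.0, ErrorModelParams(1.5, 0.5, 0.3)) > base

    def test_negative_radicand_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = sigma_ev11(3.0, 100.0, ErrorModelParams(2.0, -1.0, 0.0))
        assert out == pytest.approx(6.0)


class TestBinning:
    def test_edge_inclusivity(self):
        groups = [_group([0.0, 0.0], hkl=(0, 0, 1)),
                  _group([100.0, 100.0], hkl=(0, 0, 2))]
        bins = bin_measurements(groups, n_bins=100)
        assert bins.edges[0] == 0.0 and bins.edges[-1] == 100.0
        assert bins.counts[0] == 2 and bins.counts[99] == 2

    def test_group_lands_in_single_bin(self, rng):
        # wildly spread measurements of one reflection stay together
        g = _group(rng.uniform(0, 1000, 20), hkl=(0, 0, 1))
        other = _group([5.0, 5.0], hkl=(0, 0, 2))
        bins = bin_measurements([g, other], n_bins=100)
        assert (bins.counts > 0).sum() == 2
        assert sorted(bins.counts[bins.counts > 0]) == [2, 20]

    def test_count_conservation_excludes_singletons(self, small_groups):
        bins = bin_measurements(small_groups, n_bins=100)
        expected = sum(g.n for g in small_groups if g.n >= 2)
        assert bins.counts.sum() == expected

    def test_degenerate_range_single_bin(self):
        groups = [_group([5.0, 5.0], hkl=(0, 0, k)) for k in range(3)]
        with pytest.warns(RuntimeWarning, match="single bin"):
            bins = bin_measurements(groups, n_bins=100)
        assert bins.n_bins == 1 and bins.counts.sum() == 6


class TestTargetFunction:
    def test_matches_straight_loop(self, rng):
        groups = gaussian_groups(rng, 300, 4)
        prepared = prepare_groups(groups, n_bins=20)
        for params in (ErrorModelParams(1.1, 0.2, 0.05),
                       ErrorModelParams(0.7, 0.0, 0.3)):
            f = target_function(params, prepared)
            # independent straight-loop evaluation
            means = {g.hkl: g.mean for g in groups}
            lo = min(means.values())
            width = (max(means.values()) - lo) / 20
            d2_by_bin = {}
            for g in groups:
                b = min(int((means[g.hkl] - lo) / width), 19)
                for j in range(g.n):
                    se = sigma_ev11(g.sigmas[j], means[g.hkl], params)
                    d = normalized_deviation(g, j, se)
                    d2_by_bin.setdefault(b, []).append(d * d)
            f_ref = sum(
                len(v) ** 0.5 * ((sum(v) / len(v)) ** 0.5 - 1.0) ** 2
                for v in d2_by_bin.values()
            )
            assert f == pytest.approx(f_ref, rel=1e-10)

    def test_calibrated_data_give_small_target(self, rng):
        groups = gaussian_groups(rng, 5000, 4)
        prepared = prepare_groups(groups)
        f = target_function(ErrorModelParams(1.0, 0.0, 0.0), prepared)
        # every occupied bin has rmsd near 1
        occ = prepared.bins.counts > 0
        assert np.all(np.abs(prepared.bins.rmsd[occ] - 1.0) < 0.3)
        assert f < 0.1 * prepared.bins.weights[occ].sum()

    def test_doubling_sfac_halves_every_deviation(self, rng):
        groups = gaussian_groups(rng, 5000, 4)
        prepared = prepare_groups(groups)
        target_function(ErrorModelParams(1.0, 0.0, 0.0), prepared)
        rmsd1 = prepared.bins.rmsd.copy()
        f2 = target_function(ErrorModelParams(2.0, 0.0, 0.0), prepared)
        np.testing.assert_allclose(prepared.bins.rmsd, rmsd1 / 2.0, rtol=1e-12)
        occ = prepared.bins.counts > 0
        expected = np.sum(prepared.bins.weights[occ]
                          * (rmsd1[occ] / 2.0 - 1.0) ** 2)
        assert f2 == pytest.approx(expected, rel=1e-12)
        assert f2 == pytest.approx(0.25 * prepared.bins.weights[occ].sum(),
                                   rel=0.05)

    def test_scale_property(self, rng):
        """sigma -> c*sigma with s_fac -> s_fac/c leaves the target unchanged."""
        groups = gaussian_groups(rng, 200, 4)
        prepared = prepare_groups(groups, n_bins=10)
        f1 = target_function(ErrorModelParams(1.3, 0.0, 0.0), prepared)
        c = 7.0
        scaled = [ReflectionGroup(g.hkl, g.intensities, c * g.sigmas)
                  for g in groups]
        prepared_c = prepare_groups(scaled, n_bins=10)
        f2 = target_function(ErrorModelParams(1.3 / c, 0.0, 0.0), prepared_c)
        assert f2 == pytest.approx(f1, rel=1e-12)


class TestTargetGradient:
    def test_matches_central_finite_differences(self, rng):
        groups = gaussian_groups(rng, 400, 5)
        prepared = prepare_groups(groups, n_bins=50)
        for _ in range(20):
            params = ErrorModelParams(
                s_fac=rng.uniform(0.5, 3.0),
                s_B=rng.uniform(0.0, 2.0),
                s_add=rng.uniform(0.02, 1.0),
            )
            g = target_gradient(params, prepared)
            x = params.as_array()
            fd = np.zeros(3)
            for i in range(3):
                h = 1e-6 * max(abs(x[i]), 1.0)
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd[i] = (
                    target_function(ErrorModelParams(*xp), prepared)
                    - target_function(ErrorModelParams(*xm), prepared)
                ) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-10)

    def test_sb_gradient_vanishes_when_means_are_zero(self, rng):
        groups = [
            _group(rng.normal(0.0, 3.0, 4) - 0.0, np.full(4, 3.0), (k, 0, 0))
            for k in range(50)
        ]
        # force all group means to (numerically) zero
        groups = [
            ReflectionGroup(g.hkl, g.intensities - g.intensities.mean(),
                            g.sigmas)
            for g in groups
        ]
        prepared = prepare_groups(groups)
        g = target_gradient(ErrorModelParams(1.0, 0.5, 0.0), prepared)
        assert g[1] == pytest.approx(0.0, abs=1e-10)


class TestRefinement:
    def test_trace_non_increasing_and_final_not_worse(self, small_groups):
        prepared = prepare_groups(small_groups)
        plot = normal_probability_plot(deviations_for_plot(small_groups))
        res = refine_error_model(prepared, initialize_params(plot.slope, plot.offset))
        assert np.all(np.diff(res.trace) <= 1e-9 * np.abs(res.trace[:-1]) + 1e-12)
        assert res.trace[-1] <= res.trace[0]

    def test_restart_from_stationary_point_stops_immediately(self, small_groups):
        prepared = prepare_groups(small_groups)
        plot = normal_probability_plot(deviations_for_plot(small_groups))
        first = refine_error_model(prepared, initialize_params(plot.slope, plot.offset))
        second = refine_error_model(prepared, first.params)
        assert second.n_steps <= 2
        assert second.params.s_fac == pytest.approx(first.params.s_fac, rel=1e-4)
        assert second.params.s_add == pytest.approx(first.params.s_add, abs=1e-4)

    def test_calibrated_simulation_keeps_overall_rmsd_near_one(self, rng):
        groups = gaussian_groups(rng, 10000, 4)
        prepared = prepare_groups(groups)
        res = refine_error_model(prepared, ErrorModelParams(1.0, 0.0, 0.0))
        d = deviations_for_plot(groups, res.params)
        assert np.sqrt(np.mean(d**2)) == pytest.approx(1.0, abs=0.02)
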