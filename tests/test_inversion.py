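import numpy as np
import pytest
from scipy.optimize import lsq_linear

from deerquant.dipolar_model import DistanceAxis
from deerquant.inversion import (
    InversionConfig,
    ReliabilityRanges,
    TikhonovProblem,
    distribution_l1,
    fit_global,
    fit_single,
    jackknife_traces,
    reliability_ranges,
    second_difference_operator,
    select_alpha,
    tikhonov_nnls,
)
from deerquant.synthetic_data import (
    GroundTruthSpec,
    TraceSpec,
    fixture_ground_truth,
    make_ground_truth,
    simulate_trace,
    simulate_trace_set,
)
from deerquant.traces import TraceSet, truncate_end


@pytest.fixture(scope="module")
def single_gaussian(default_axis):
    return make_ground_truth(GroundTruthSpec(((4.0, 0.3, 1.0),), default_axis))


class TestTikhonovSolver:
    def test_matches_bounded_least_squares_oracle_on_toy_problems(self):
        """The inner active-set solve must agree with an independent
        constrained-least-squares oracle (BVLS) on 20-point problems."""
        rng = np.random.default_rng(0)
        reg = second_difference_operator(20, zero_boundary=False)
        for trial in range(5):
            a = rng.normal(size=(30, 20))
            b = a @ np.abs(rng.normal(size=20)) + 0.01 * rng.normal(size=30)
            for alpha in (0.01, 0.3, 2.0):
                ours = tikhonov_nnls(a, b, reg, alpha)
                stacked = np.vstack([a, alpha * reg])
                rhs = np.concatenate([b, np.zeros(reg.shape[0])])
                oracle = lsq_linear(stacked, rhs, bounds=(0.0, np.inf),
                                    method="bvls").x
                assert np.abs(ours - oracle).max() < 1e-6

    def test_solution_nonnegative(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(40, 20))
        b = rng.normal(size=40)
        x = tikhonov_nnls(a, b, second_difference_operator(20), 0.5)
        assert np.all(x >= 0)


class TestAlphaSelection:
    def _problem(self, noise_sd, seed, default_axis):
        from deerquant.dipolar_model import build_kernel
        from deerquant.inversion import _assemble

        dist = fixture_ground_truth("exp19C", default_axis)
        tr = simulate_trace(
            dist, TraceSpec(t_max=4.0, noise_sd=noise_sd, seed=seed)
        ).with_noise_estimate()
        ker = build_kernel(tr.time_us, default_axis).matrix
        theta = np.array([0.3, 0.05, 1.0])
        a, b = _assemble(theta, [tr], [ker], [max(tr.noise_sd, 1e-5)], 3.0,
                         default_axis)
        return TikhonovProblem(a, b, second_difference_operator(len(default_axis)))

    def test_curve_has_grid_length(self, default_axis):
        grid = np.logspace(-4, 4, 25)
        alpha, curve = select_alpha(self._problem(0.005, 0, default_axis),
                                    "srgcv", grid)
        assert curve.shape == grid.shape
        assert alpha in grid

    def test_more_noise_means_more_effective_smoothing(self, default_axis):
        """The scale-free smoothing strength alpha * sigma must trend upward
        when the noise level rises tenfold (noise-normalised residuals make
        the selected alpha itself scale with 1/sigma)."""
        strengths = {}
        for noise in (0.002, 0.02):
            vals = []
            for seed in range(10):
                problem = self._problem(noise, 100 + seed, default_axis)
                alpha, _ = select_alpha(problem, "srgcv")
                vals.append(alpha * noise)
            strengths[noise] = np.median(vals)
        assert strengths[0.02] > strengths[0.002]

    def test_too_small_grid_rejected(self, default_axis):
        with pytest.raises(ValueError):
            select_alpha(self._problem(0.005, 0, default_axis), "gcv",
                         np.logspace(-2, 2, 10))

    def test_unknown_criterion_rejected(self, default_axis):
        with pytest.raises(ValueError):
            select_alpha(self._problem(0.005, 0, default_axis), "aic")


class TestSingleTraceFit:
    def test_noiseless_gaussian_recovered(self, single_gaussian, default_axis):
        tr = simulate_trace(
            single_gaussian,
            TraceSpec(t_max=6.0, lam=0.3, bg_k=0.05, noise_sd=0.0, seed=1),
        )
        fit = fit_single(tr, default_axis)
        assert fit.distribution.mean() == pytest.approx(4.0, abs=0.05)
        assert fit.distribution.std() == pytest.approx(0.3, abs=0.05)
        # regularisation bias below noise floor on clean data
        assert np.sqrt(np.mean(fit.residuals[0] ** 2)) < 1e-3

    def test_modulation_depth_recovered(self, single_gaussian, default_axis):
        tr = simulate_trace(
            single_gaussian,
            TraceSpec(t_max=6.0, lam=0.3, bg_k=0.05, noise_sd=0.005, seed=2),
        )
        fit = fit_single(tr, default_axis)
        assert 0.27 <= fit.trace_params[0].lam <= 0.33

    def test_background_only_data_flagged_low_depth(self, single_gaussian, default_axis):
        tr = simulate_trace(
            single_gaussian,
            TraceSpec(t_max=4.0, lam=0.01, bg_k=0.05, noise_sd=0.002, seed=3),
        )
        fit = fit_single(tr, default_axis)
        assert any("low modulation depth" in f for f in fit.flags)

    def test_end_truncation_barely_moves_the_mean(self, single_gaussian, default_axis):
        tr = simulate_trace(
            single_gaussian,
            TraceSpec(t_max=6.0, lam=0.3, bg_k=0.05, noise_sd=0.0, seed=4),
        )
        full = fit_single(tr, default_axis)
        cut = fit_single(truncate_end(tr, 10), default_axis)
        assert abs(full.distribution.mean() - cut.distribution.mean()) < 0.05


class TestGlobalFit:
    def test_singleton_set_equals_single_trace_fit(self, single_gaussian, default_axis):
        tr = simulate_trace(
            single_gaussian, TraceSpec(t_max=4.0, noise_sd=0.005, seed=5)
        )
        a = fit_single(tr, default_axis)
        b = fit_global(TraceSet([tr]), default_axis)
        assert np.abs(a.distribution.density - b.distribution.density).max() < 1e-9
        assert a.alpha == b.alpha

    def test_bimodal_fixture_modes_recovered(self, population_recovery):
        fit = population_recovery["exp19C"][0]["fit"]
        dist = fit.distribution
        short = dist.r[dist.r < 4.15][np.argmax(dist.density[dist.r < 4.15])]
        long_ = dist.r[dist.r >= 4.15][np.argmax(dist.density[dist.r >= 4.15])]
        assert short == pytest.approx(3.3, abs=0.1)
        assert long_ == pytest.approx(5.0, abs=0.15)

    def test_recovered_distribution_nonnegative_and_normalised(self, population_recovery):
        for entries in population_recovery.values():
            dist = entries[0]["fit"].distribution
            assert np.all(dist.density >= 0)
            assert dist.integral() == pytest.approx(1.0, abs=1e-9)

    def test_residuals_pass_runs_test_for_whiteness(self, population_recovery):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        fit = population_recovery["exp19C"][0]["fit"]
        for res in fit.residuals:
            _, pvalue = runstest_1samp(res, cutoff=0.0)
            assert pvalue > 0.01

    def test_component_means_unbiased_across_replicates(self, population_recovery):
        mu1 = np.array([e["mu1"] for e in population_recovery["exp19C"]])
        mu2 = np.array([e["mu2"] for e in population_recovery["exp19C"]])
        assert abs(mu1.mean() - 3.3) < 0.05
        assert abs(mu2.mean() - 5.0) < 0.1

    def test_reconstruction_error_degrades_monotonically_with_noise(
        self, single_gaussian, default_axis
    ):
        levels = (0.002, 0.005, 0.01, 0.02)
        mean_l1 = []
        for noise in levels:
            errs = []
            for seed in (0, 1, 2):
                tr = simulate_trace(
                    single_gaussian,
                    TraceSpec(t_max=4.0, lam=0.3, bg_k=0.05, noise_sd=noise,
                              seed=200 + seed),
                )
                fit = fit_single(tr, default_axis)
                errs.append(distribution_l1(fit.distribution, single_gaussian))
            mean_l1.append(np.mean(errs))
        slope = np.polyfit(np.log(levels), mean_l1, 1)[0]
        assert slope > 0
        assert mean_l1[-1] > mean_l1[0]


class TestReliability:
    def test_default_constants_at_two_microseconds(self):
        rr = reliability_ranges(2.0)
        assert rr.r_shape == pytest.approx(5.0)
        assert rr.r_mean_width == pytest.approx(6.0)
        assert rr.r_mean == pytest.approx(7.0)

    def test_cube_root_scaling_doubles_at_sixteen_microseconds(self):
        assert reliability_ranges(16.0).r_shape == pytest.approx(10.0)

    def test_ordering_invariant(self):
        for t_max in (0.5, 2.0, 7.5, 20.0):
            rr = reliability_ranges(t_max)
            assert rr.r_shape < rr.r_mean_width < rr.r_mean

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reliability_ranges(0.0)
        with pytest.raises(ValueError):
            ReliabilityRanges(6.0, 5.0, 7.0)


class TestJackknife:
    def test_duplicated_traces_give_zero_dispersion(self, single_gaussian):
        tr = simulate_trace(
            single_gaussian, TraceSpec(t_max=2.0, dt=0.03, noise_sd=0.005, seed=9)
        )
        fits, summary = jackknife_traces(TraceSet([tr, tr, tr, tr]))
        assert len(fits) == 4
        assert summary["max_pairwise_l1"] < 1e-6

    def test_leave_one_out_stability_on_fixture_data(self, default_axis):
        dist = fixture_ground_truth("exp19C", default_axis)
        specs = [
            TraceSpec(t_max=tm, dt=0.024, noise_sd=0.005, seed=30 + i)
            for i, tm in enumerate((2.0, 4.0, 6.0, 7.5))
        ]
        ts = simulate_trace_set(dist, specs)
        fits, summary = jackknife_traces(ts, default_axis)
        assert len(fits) == len(ts)
        assert summary["max_pairwise_l1"] < 0.15

    def test_requires_three_traces(self, single_gaussian):
        tr = simulate_trace(single_gaussian, TraceSpec(t_max=2.0, dt=0.03, seed=1))
        with pytest.raises(ValueError):
            jackknife_traces(TraceSet([tr, tr]))
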