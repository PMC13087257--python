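import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deerquant.dipolar_model import (
    BackgroundModel,
    DistanceAxis,
    DistanceDistribution,
    ModulationParams,
    background_value,
    build_kernel,
    dipolar_frequency,
    dipolar_signal,
    kernel_value,
    kernel_value_quadrature,
)


def brute_force_kernel(t, r, n_grid=100_001):
    """Independent oracle: trapezoidal powder average on a dense u-grid."""
    u = np.linspace(0.0, 1.0, n_grid)
    omega = 2.0 * np.pi * dipolar_frequency(r)
    return np.trapezoid(np.cos(omega * np.outer(np.atleast_1d(t), 1.0 - 3.0 * u**2)), u, axis=1)


class TestDipolarFrequency:
    @pytest.mark.parametrize("r,expected", [(1.0, 52.04), (2.0, 6.505)])
    def test_point_dipole_values(self, r, expected):
        assert dipolar_frequency(r) == pytest.approx(expected, abs=1e-9)

    def test_monotone_decreasing(self):
        r = np.linspace(1.0, 8.0, 50)
        assert np.all(np.diff(dipolar_frequency(r)) < 0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_frequency(0.0)


class TestKernel:
    @pytest.mark.parametrize("r", [2.0, 3.0, 5.0])
    def test_unity_at_time_zero(self, r):
        assert kernel_value(0.0, r) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("r", [1.5, 2.0, 3.3, 5.0, 8.0])
    def test_closed_form_matches_brute_force_quadrature(self, r):
        t = np.linspace(0.0, 8.0, 400)
        assert np.abs(kernel_value(t, r) - brute_force_kernel(t, r)).max() < 1e-6

    def test_closed_form_matches_gauss_legendre(self):
        t = np.linspace(0.0, 8.0, 200)
        for r in (1.5, 3.0, 6.0):
            assert np.abs(kernel_value(t, r) - kernel_value_quadrature(t, r)).max() < 1e-6

    def test_long_time_powder_decay(self):
        assert abs(kernel_value(10.0, 2.0)) <= 0.05

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(-0.1, 3.0)

    @given(st.floats(0.0, 10.0), st.floats(1.5, 8.0))
    def test_bounded_magnitude(self, t, r):
        assert abs(kernel_value(t, r)) <= 1.0 + 1e-12


class TestKernelMatrix:
    def test_point_mass_reproduces_kernel(self):
        axis = DistanceAxis(1.5, 9.0, 0.002)
        t = np.linspace(0.0, 6.0, 100)
        mat = build_kernel(t, axis)
        sd = 1e-3
        dens = np.exp(-0.5 * ((axis.values - 3.0) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        dist = DistanceDistribution(axis, dens).normalized()
        assert np.abs(mat.form_factor(dist) - kernel_value(t, 3.0)).max() < 1e-3

    def test_time_zero_row_integrates_any_density_to_one(self, default_axis):
        mat = build_kernel(np.array([0.0, 1.0]), default_axis)
        rng = np.random.default_rng(7)
        dens = rng.uniform(0.0, 1.0, len(default_axis))
        dist = DistanceDistribution(default_axis, dens).normalized()
        assert mat.form_factor(dist)[0] == pytest.approx(1.0, abs=1e-6)

    def test_axis_refinement_converges_for_smooth_density(self):
        t = np.linspace(0.0, 5.0, 80)

        def form(step):
            axis = DistanceAxis(1.5, 9.0, step)
            r = axis.values
            dens = np.exp(-0.5 * ((r - 4.0) / 0.4) ** 2)
            dist = DistanceDistribution(axis, dens).normalized()
            return build_kernel(t, axis).form_factor(dist)

        assert np.abs(form(0.05) - form(0.025)).max() < 1e-4

    def test_unsorted_time_axis_rejected(self, default_axis):
        with pytest.raises(ValueError):
            build_kernel(np.array([0.0, 2.0, 1.0]), default_axis)


class TestBackground:
    def test_zero_rate_is_flat(self):
        bg = BackgroundModel(k=0.0, d=3.0)
        t = np.linspace(0.0, 8.0, 50)
        assert np.all(background_value(t, bg) == 1.0)

    @pytest.mark.parametrize(
        "d,t,expected",
        [(3.0, 1.0, np.exp(-0.1)), (2.0, 8.0, np.exp(-0.1 * 8.0 ** (2.0 / 3.0)))],
    )
    def test_stretched_exponential_values(self, d, t, expected):
        assert background_value(t, BackgroundModel(k=0.1, d=d)) == pytest.approx(expected)

    def test_monotone_nonincreasing(self):
        t = np.linspace(0.0, 10.0, 200)
        b = background_value(t, BackgroundModel(k=0.3, d=2.5))
        assert np.all(np.diff(b) <= 0)

    def test_invalid_stretch_dimension_rejected(self):
        with pytest.raises(ValueError):
            BackgroundModel(k=0.1, d=7.0)


class TestDipolarSignal:
    def _gaussian(self, axis, mu, sd):
        dens = np.exp(-0.5 * ((axis.values - mu) / sd) ** 2)
        return DistanceDistribution(axis, dens).normalized()

    def test_zero_modulation_depth_limit(self, default_axis):
        dist = self._gaussian(default_axis, 4.0, 0.3)
        t = np.linspace(0.0, 6.0, 100)
        bg = BackgroundModel(k=0.2, d=3.0)
        v = dipolar_signal(dist, ModulationParams(lam=1e-9, v0=1.0), bg, t)
        assert np.abs(v - background_value(t, bg)).max() < 1e-8

    def test_signal_starts_at_v0_and_stays_above_floor(self, default_axis):
        dist = self._gaussian(default_axis, 4.0, 0.3)
        t = np.linspace(0.0, 6.0, 200)
        v = dipolar_signal(dist, ModulationParams(lam=0.3, v0=2.0),
                           BackgroundModel(k=0.0, d=3.0), t)
        assert v[0] == pytest.approx(2.0, abs=1e-9)
        # K >= -0.5, so the signal never drops below V0 (1 - 1.5 lambda),
        # and the oscillation-averaged tail settles at V0 (1 - lambda)
        assert np.all(v >= 2.0 * (1.0 - 1.5 * 0.3) - 1e-6)
        assert np.mean(v[-20:]) == pytest.approx(2.0 * (1.0 - 0.3), abs=1e-3)

    def test_two_component_mixture_matches_kernel_combination(self, default_axis):
        sd = 0.01
        r = default_axis.values
        dens = 0.5 * (
            np.exp(-0.5 * ((r - 3.3) / sd) ** 2) + np.exp(-0.5 * ((r - 5.0) / sd) ** 2)
        )
        dist = DistanceDistribution(default_axis, dens).normalized()
        t = np.linspace(0.0, 6.0, 150)
        v = dipolar_signal(dist, ModulationParams(lam=0.3, v0=1.0),
                           BackgroundModel(k=0.0, d=3.0), t)
        form = 0.5 * (brute_force_kernel(t, 3.3) + brute_force_kernel(t, 5.0))
        assert np.abs(v - (0.7 + 0.3 * form)).max() < 1e-4

    def test_linearity_in_the_distribution(self, default_axis):
        d1 = self._gaussian(default_axis, 3.3, 0.5)
        d2 = self._gaussian(default_axis, 5.0, 0.3)
        a = 0.37
        mix = DistanceDistribution(
            default_axis, a * d1.density + (1 - a) * d2.density
        )
        t = np.linspace(0.0, 7.5, 100)
        mod, bg = ModulationParams(lam=0.4, v0=1.1), BackgroundModel(k=0.07, d=3.0)
        v_mix = dipolar_signal(mix, mod, bg, t)
        v_lin = a * dipolar_signal(d1, mod, bg, t) + (1 - a) * dipolar_signal(d2, mod, bg, t)
        assert np.abs(v_mix - v_lin).max() < 1e-9

    def test_negative_time_axis_rejected(self, default_axis):
        dist = self._gaussian(default_axis, 4.0, 0.3)
        with pytest.raises(ValueError):
            dipolar_signal(dist, ModulationParams(), BackgroundModel(),
                           np.array([-1.0, 0.0, 1.0]))


class TestDistanceAxis:
    def test_point_count_follows_definition(self):
        axis = DistanceAxis(1.5, 9.0, 0.05)
        assert len(axis) == 151
        assert axis.values[0] == 1.5
        assert axis.values[-1] == pytest.approx(9.0)

    @pytest.mark.parametrize("bad", [{"r_min": 0.5}, {"r_max": 1.0}, {"step": -0.1}])
    def test_invalid_axes_rejected(self, bad):
        kwargs = {"r_min": 1.5, "r_max": 9.0, "step": 0.05, **bad}
        with pytest.raises(ValueError):
            DistanceAxis(**kwargs)
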