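"""Morlet transform, smoothing, cone of influence, and coherence estimator."""

import numpy as np
import pytest
from scipy.integrate import quad

from physiocoh import (SampledSeries, build_scale_grid, cone_of_influence,
                       cross_wavelet, cwt, fourier_factor, morlet, smooth_field,
                       wtc)
from physiocoh.series import DegenerateSignalError

from conftest import direct_cwt, lagged_sine_pair


class TestMorlet:
    def test_value_at_origin_is_pi_quarter(self):
        assert morlet(0.0) == pytest.approx(np.pi ** (-0.25), abs=1e-12)
        assert morlet(0.0).imag == 0.0

    def test_envelope_is_even(self):
        eta = np.linspace(-5, 5, 41)
        assert np.allclose(np.abs(morlet(eta)), np.abs(morlet(-eta)))

    def test_unit_energy_by_quadrature(self):
        energy, _ = quad(lambda e: np.abs(morlet(e)) ** 2, -8, 8)
        assert energy == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_omega0(self):
        with pytest.raises(ValueError):
            morlet(0.0, omega0=0.0)


class TestScaleGrid:
    def test_period_scale_ratio_matches_printed_value(self):
        assert round(fourier_factor(6.0), 2) == 1.03

    def test_default_grid_covers_analysis_bands(self):
        g = build_scale_grid(0.72, 1200)
        assert g.fourier_periods[0] == pytest.approx(1.49, abs=0.01)
        assert g.frequencies[0] > 0.4 and g.frequencies[-1] < 0.02

    def test_grid_is_dyadic(self):
        g = build_scale_grid(0.72, 1200, dj=1.0 / 12.0)
        step = int(round(1 / g.dj))
        assert np.allclose(g.scales[step:] / g.scales[:-step], 2.0)
        # constant period/scale ratio across the grid
        assert np.allclose(g.fourier_periods / g.scales, fourier_factor())

    def test_subresolution_s0_rejected(self):
        with pytest.raises(ValueError):
            build_scale_grid(0.72, 1200, s0=0.1)


class TestConeOfInfluence:
    def test_zero_at_edges_and_symmetric(self):
        coi = cone_of_influence(512, 0.72)
        assert coi[0] == 0.0 and coi[-1] == 0.0
        assert np.allclose(coi, coi[::-1])

    def test_trustworthy_window_for_50s_period(self):
        # invert coi(t) = ff * min(t, T-t)/sqrt(2) at period 50 s
        n, dt = 1200, 0.72
        coi = cone_of_influence(n, dt)
        t = dt * np.arange(n)
        inside = t[coi > 50.0]
        t_enter = 50.0 * np.sqrt(2) / fourier_factor()
        assert abs(inside[0] - t_enter) <= dt
        assert abs(inside[-1] - (t[-1] - t_enter)) <= dt


class TestCWT:
    def test_zero_input_gives_zero_coefficients(self):
        g = build_scale_grid(0.72, 128)
        W = cwt(SampledSeries(np.zeros(128), dt=0.72), g)
        assert np.all(W.coeffs == 0)

    def test_power_peaks_at_matching_scale(self):
        n, dt = 1024, 0.72
        t = dt * np.arange(n)
        g = build_scale_grid(dt, n)
        W = cwt(SampledSeries(np.sin(2 * np.pi * 0.1 * t), dt=dt), g)
        mean_power = (np.abs(W.coeffs) ** 2).mean(axis=1)
        peak_period = g.fourier_periods[np.argmax(mean_power)]
        nearest = g.fourier_periods[np.argmin(np.abs(g.fourier_periods - 10.0))]
        assert peak_period == pytest.approx(nearest)

    def test_matches_direct_double_sum(self, rng):
        n, dt = 128, 0.72
        x = rng.normal(size=n)
        g = build_scale_grid(dt, n)
        fast = cwt(SampledSeries(x, dt=dt), g).coeffs
        slow = direct_cwt(x, dt, g)
        rel = np.abs(fast - slow) / np.abs(slow)
        assert rel.max() < 1e-8

    def test_length_mismatch_rejected(self):
        g = build_scale_grid(0.72, 400)
        x = SampledSeries(np.ones(64), dt=0.72)
        y = SampledSeries(np.zeros(400), dt=0.72)
        with pytest.raises((ValueError, DegenerateSignalError)):
            wtc(x, y, g)


class TestSmoothing:
    def test_constant_field_unchanged(self, small_grid):
        field = np.full((small_grid.n_scales, 400), 3.7)
        out = smooth_field(field, small_grid, 0.72)
        assert np.allclose(out, 3.7, atol=1e-10)

    def test_impulse_mass_conserved_mid_field(self, small_grid):
        field = np.zeros((small_grid.n_scales, 400))
        j = small_grid.n_scales // 2
        field[j, 200] = 1.0
        out = smooth_field(field, small_grid, 0.72)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        # spread bounded by ~2 time-kernel sds at the widest affected scale
        sd_samp = small_grid.scales[j + 4] / np.sqrt(2) / 0.72
        support = np.abs(np.arange(400) - 200) > 4 * sd_samp
        assert np.abs(out[:, support]).max() < 1e-4

    def test_linearity(self, small_grid, rng):
        field = rng.normal(size=(small_grid.n_scales, 400))
        a = smooth_field(2.0 * field, small_grid, 0.72)
        b = 2.0 * smooth_field(field, small_grid, 0.72)
        assert np.allclose(a, b)


class TestCrossWavelet:
    def test_self_cross_has_zero_phase(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400), dt=0.72)
        W = cwt(x, small_grid)
        XW = cross_wavelet(W, W)
        assert np.allclose(XW.phase, 0.0)
        assert np.allclose(XW.power, np.abs(W.coeffs) ** 2)

    def test_argument_swap_conjugates(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400), dt=0.72)
        y = SampledSeries(rng.normal(size=400), dt=0.72)
        WX, WY = cwt(x, small_grid), cwt(y, small_grid)
        assert np.allclose(cross_wavelet(WX, WY).coeffs,
                           np.conj(cross_wavelet(WY, WX).coeffs))

    def test_lagged_sinusoid_phase(self):
        # delay of 2 s at 0.1 Hz -> phase 2*pi*0.1*2 = 1.257 rad at the 10 s scale
        lead, trail = lagged_sine_pair(0.1, 2.0, n=1024, noise_sd=0.0)
        g = build_scale_grid(0.72, 1024)
        XW = cross_wavelet(cwt(lead, g), cwt(trail, g))
        j = np.argmin(np.abs(g.frequencies - 0.1))
        oc = XW.outside_cone()
        mean_phase = np.angle(np.mean(np.exp(1j * XW.phase[j, oc[j]])))
        assert mean_phase == pytest.approx(2 * np.pi * 0.1 * 2.0, abs=np.pi / 16)


class TestWTC:
    def test_self_coherence_is_unity(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400), dt=0.72)
        coh = wtc(x, x, small_grid)
        assert np.abs(coh.r2 - 1.0).max() < 1e-9

    def test_affine_invariance(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400), dt=0.72)
        y = SampledSeries(rng.normal(size=400), dt=0.72)
        base = wtc(x, y, small_grid)
        scaled = wtc(x.with_values(2.5 * x.values + 7.0),
                     y.with_values(0.3 * y.values - 4.0), small_grid)
        assert np.allclose(base.r2, scaled.r2, atol=1e-10)
        assert np.allclose(base.phase, scaled.phase, atol=1e-8)
        # a negative gain flips the cross-spectrum phase by pi but not R^2
        flipped = wtc(x.with_values(-1.0 * x.values), y, small_grid)
        assert np.allclose(base.r2, flipped.r2, atol=1e-10)
        rot = np.angle(np.exp(1j * (flipped.phase - base.phase)))
        assert np.allclose(np.abs(rot), np.pi, atol=1e-8)

    def test_without_smoothing_coherence_degenerates_to_one(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400), dt=0.72)
        y = SampledSeries(rng.normal(size=400), dt=0.72)
        degenerate = wtc(x, y, small_grid, smooth_time=False, smooth_scale=False)
        assert np.abs(degenerate.r2 - 1.0).max() < 1e-7
        smoothed = wtc(x, y, small_grid)
        assert smoothed.r2.mean() < 0.9  # smoothing is actually applied

    def test_strong_coupling_recovered(self):
        lead, trail = lagged_sine_pair(0.1, 0.0, n=1200, noise_sd=0.05)
        g = build_scale_grid(0.72, 1200)
        coh = wtc(lead, trail, g)
        j = np.argmin(np.abs(g.frequencies - 0.1))
        oc = coh.outside_cone()
        assert coh.r2[j, oc[j]].mean() > 0.9
        phase = np.angle(np.mean(np.exp(1j * coh.phase[j, oc[j]])))
        assert abs(phase) < np.pi / 16

    def test_constant_input_rejected(self, small_grid):
        x = SampledSeries(np.ones(400), dt=0.72)
        y = SampledSeries(np.arange(400, dtype=float), dt=0.72)
        with pytest.raises(DegenerateSignalError):
            wtc(x, y, small_grid)

    def test_r2_bounded_unit_interval(self, small_grid, rng):
        x = SampledSeries(rng.normal(size=400).cumsum(), dt=0.72)
        y = SampledSeries(rng.normal(size=400), dt=0.72)
        coh = wtc(x, y, small_grid)
        assert coh.r2.min() >= 0.0 and coh.r2.max() <= 1.0
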