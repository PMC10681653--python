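"""Ground-truth properties of the synthetic-data generator."""

import json

import numpy as np
import pytest
from scipy.signal import periodogram

from physiocoh import (CouplingScenario, SampledSeries, build_scale_grid,
                       compute_rvt, detect_breath_extrema, detect_pulse_peaks,
                       fit_ar, gen_ar1_series, gen_coupled_pair,
                       gen_pulse_recording, gen_respiration_recording, gen_study,
                       wtc)
from physiocoh.significance import NonstationaryModelError


class TestAR1Generator:
    def test_white_noise_has_no_lag1_autocorrelation(self):
        x = gen_ar1_series(0.0, 1.0, 1000, dt=1.0, seed=4).values
        v = x - x.mean()
        assert abs((v[:-1] @ v[1:]) / (v @ v)) < 0.1

    def test_stationary_variance_closed_form(self):
        x = gen_ar1_series(0.8, 1.0, 5000, dt=1.0, seed=5).values
        expected = 1.0 / (1 - 0.8**2)  # = 2.778
        assert x.var() == pytest.approx(expected, rel=0.15)

    def test_noise_free_recursion_decays_geometrically(self):
        x = gen_ar1_series(0.5, 0.0, 10, dt=1.0, seed=0, x0=1.0).values
        assert np.allclose(x, 0.5 ** np.arange(10))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(NonstationaryModelError):
            gen_ar1_series(1.0, 1.0, 100, dt=1.0)
        with pytest.raises(ValueError):
            gen_ar1_series(0.5, 1.0, 1, dt=1.0)

    def test_fitted_phi_tracks_truth_at_scan_length(self):
        # averaged over seeds, Yule-Walker phi-hat within 0.05 of truth at n=1200
        phis = [fit_ar(gen_ar1_series(0.5, 1.0, 1200, dt=0.72, seed=s)
                       ).coefficients[0] for s in range(100)]
        assert np.mean(phis) == pytest.approx(0.5, abs=0.05)


class TestPulseGenerator:
    def test_constant_interval_peak_spacing(self):
        prof = SampledSeries(np.ones(60), dt=1.0)
        rec = gen_pulse_recording(prof, physio_rate=400.0, seed=0)
        peaks = detect_pulse_peaks(rec)
        assert 58 <= len(peaks) <= 60
        spacing = np.diff(peaks.times)
        assert np.abs(spacing - 1.0).max() <= 0.0025  # one sample at 400 Hz

    def test_modulated_intervals_recovered_spectrally(self):
        t = np.arange(600)
        prof = SampledSeries(1.0 + 0.1 * np.sin(2 * np.pi * 0.1 * t), dt=1.0)
        rec = gen_pulse_recording(prof, physio_rate=200.0, seed=0)
        peaks = detect_pulse_peaks(rec)
        intervals = np.diff(peaks.times)
        # resample recovered intervals to a uniform 1 s grid
        mid = peaks.times[:-1] + intervals / 2
        grid_t = np.arange(mid[0], mid[-1], 1.0)
        iv = np.interp(grid_t, mid, intervals)
        f, p = periodogram(iv - iv.mean(), fs=1.0)
        assert f[np.argmax(p)] == pytest.approx(0.1, abs=0.02)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            gen_pulse_recording(SampledSeries(np.empty(0), dt=1.0), 400.0)

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError):
            gen_pulse_recording(SampledSeries(np.full(10, 2.5), dt=1.0), 400.0)


class TestRespirationGenerator:
    def test_constant_profile_round_trips(self):
        prof = SampledSeries(np.full(300, 0.5), dt=1.0)
        rec = gen_respiration_recording(prof, physio_rate=100.0, seed=0)
        maxima, minima = detect_breath_extrema(rec)
        frames = np.arange(10.0, 290.0, 0.72)
        rvt = compute_rvt(maxima, minima, frames)
        assert np.abs(rvt.values / 0.5 - 1.0).max() < 0.05

    def test_step_profile_recovered(self):
        vals = np.where(np.arange(300) < 150, 0.4, 0.8)
        rec = gen_respiration_recording(SampledSeries(vals, dt=1.0), 100.0, seed=0)
        maxima, minima = detect_breath_extrema(rec)
        frames = np.arange(10.0, 290.0, 1.0)
        rvt = compute_rvt(maxima, minima, frames).values
        before, after = rvt[frames < 140], rvt[frames > 160]
        assert after.mean() - before.mean() > 0.3

    def test_aliasing_rate_rejected(self):
        prof = SampledSeries(np.full(60, 0.5), dt=1.0)
        with pytest.raises(ValueError):
            gen_respiration_recording(prof, physio_rate=0.4)

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ValueError):
            gen_respiration_recording(SampledSeries(np.zeros(60), dt=1.0), 100.0)


class TestCoupledPair:
    def test_zero_strength_gives_independent_series(self):
        scn = CouplingScenario(n_frames=1200, coupling_strength=0.0, seed=9)
        bold, phys, _ = gen_coupled_pair(scn)
        r = np.corrcoef(bold.values, phys.values)[0, 1]
        assert abs(r) < 0.1

    def test_strong_full_record_coupling_gives_unit_coherence(self):
        scn = CouplingScenario(n_frames=1200, coupling_strength=10.0,
                               coupling_freq=0.1, phase_lag=0.0, seed=10)
        bold, phys, truth = gen_coupled_pair(scn)
        g = build_scale_grid(scn.dt_frames, scn.n_frames)
        coh = wtc(phys, bold, g)
        j = np.argmin(np.abs(g.frequencies - truth["coupling_freq"]))
        oc = coh.outside_cone()
        assert coh.r2[j, oc[j]].mean() > 0.95
        phase = np.angle(np.mean(np.exp(1j * coh.phase[j, oc[j]])))
        assert abs(phase) < np.pi / 16

    def test_quarter_period_lag_recovered_by_xcorr(self):
        from physiocoh import BandSpec, xcorr_peak_lag
        scn = CouplingScenario(n_frames=1200, coupling_strength=3.0,
                               coupling_freq=0.1, phase_lag=np.pi / 2, seed=11)
        bold, phys, truth = gen_coupled_pair(scn)
        assert truth["lag_seconds"] == pytest.approx(2.5)
        lag = xcorr_peak_lag(bold, phys, BandSpec("c", 0.05, 0.15), max_lag=5.0)
        assert lag == pytest.approx(2.5, abs=scn.dt_frames)

    def test_above_nyquist_frequency_rejected(self):
        with pytest.raises(ValueError):
            CouplingScenario(coupling_freq=0.8)  # Nyquist at TR 0.72 is ~0.694

    def test_frequency_and_lag_recovered_across_seeds(self):
        # high-SNR recovery of the injected frequency (nearest scale) and lag
        n, dt, f, lag = 400, 0.72, 0.1, np.pi / 2
        g = build_scale_grid(dt, n, dj=1.0 / 8.0)
        target_j = np.argmin(np.abs(g.frequencies - f))
        hits = 0
        for seed in range(12):
            scn = CouplingScenario(n_frames=n, coupling_strength=5.0,
                                   coupling_freq=f, phase_lag=lag, seed=seed)
            bold, phys, _ = gen_coupled_pair(scn)
            coh = wtc(phys, bold, g)
            oc = coh.outside_cone()
            mean_r2 = np.array([coh.r2[j, oc[j]].mean() if oc[j].any() else 0.0
                                for j in range(g.n_scales)])
            j_hat = int(np.argmax(mean_r2))
            phase = np.angle(np.mean(np.exp(1j * coh.phase[target_j, oc[target_j]])))
            # generator delays physio by phase_lag, so measured phase = -phase_lag
            lag_hat = -phase
            if abs(j_hat - target_j) <= 1 and abs(lag_hat - lag) < np.pi / 8:
                hits += 1
        assert hits >= 11


@pytest.fixture(scope="module")
def small_scn():
    return CouplingScenario(n_frames=300, dt_frames=0.72, physio_rate=100.0,
                            coupling_strength=2.0, coupling_freq=0.1)


class TestStudyGenerator:
    def test_round_trip_files(self, tmp_path, small_scn):
        bundle = gen_study(3, small_scn, out_dir=tmp_path / "study", seed=1)
        assert len(bundle.subjects) == 3
        for sub in bundle.subjects:
            assert bundle.pulse_path(sub).exists()
            assert bundle.resp_path(sub).exists()
            assert bundle.bold_path(sub).exists()
        manifest = json.loads((tmp_path / "study" / "manifest.json").read_text())
        assert set(manifest["subjects"]) == set(bundle.subjects)
        assert manifest["networks"] == ["DAN", "DMN", "FPN", "LN", "SMN", "VAN", "VN"]

    def test_same_seed_byte_identical(self, tmp_path, small_scn):
        a = gen_study(2, small_scn, out_dir=tmp_path / "a", seed=7)
        b = gen_study(2, small_scn, out_dir=tmp_path / "b", seed=7)
        for sub in a.subjects:
            assert a.pulse_path(sub).read_bytes() == b.pulse_path(sub).read_bytes()
            assert a.bold_path(sub).read_bytes() == b.bold_path(sub).read_bytes()

    def test_cohort_size_floor(self, tmp_path, small_scn):
        with pytest.raises(ValueError):
            gen_study(1, small_scn, out_dir=tmp_path / "x", seed=0)
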