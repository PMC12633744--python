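"""Spectral extraction: Welch spectra, smoothing, fundamental tracking,
harmonic profiles and peak detection."""

import numpy as np
import pytest
from scipy import signal as ssig

from syrinx_resonance import (
    CallRecording,
    average_spectra,
    central_segment,
    cepstral_smooth,
    detect_peaks,
    estimate_fundamental,
    harmonic_amplitudes,
    lpc_envelope,
    power_spectrum,
)
from syrinx_resonance.spectra import PowerSpectrum
from syrinx_resonance.synth import CallSpec, hat_contour, plant_peak_spectrum, synthesize_call

FS = 44100


def tone(freqs_amps, duration=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return CallRecording(x / np.max(np.abs(x)) * 0.9, fs)


class TestPowerSpectrum:
    def test_pure_tone_peak_position(self):
        spec = power_spectrum(tone([(3000.0, 1.0)]))
        bin_width = spec.frequencies_hz[1] - spec.frequencies_hz[0]
        assert abs(spec.peak_hz - 3000.0) <= bin_width

    def test_white_noise_flat(self, rng):
        rec = CallRecording(rng.standard_normal(3 * FS) * 0.3, FS)
        spec = power_spectrum(rec)
        assert spec.level_db.max() - spec.level_db.min() < 10.0

    def test_amplitude_ratio_in_db(self):
        spec = power_spectrum(tone([(1000.0, 1.0), (2000.0, 0.1)], duration=2.0))
        diff = spec.level_at(2000.0) - spec.level_at(1000.0)
        assert diff == pytest.approx(-20.0, abs=1.0)

    def test_normalised_to_zero_db(self):
        spec = power_spectrum(tone([(1500.0, 0.5)]))
        assert spec.level_db.max() == pytest.approx(0.0, abs=1e-9)

    def test_too_short_recording_rejected(self):
        rec = CallRecording(np.ones(1024), 44100)
        with pytest.raises(ValueError, match="shorter than one window"):
            power_spectrum(rec, window_s=0.5)

    def test_gain_invariance(self, rng):
        x = rng.standard_normal(FS) * 0.1
        s1 = power_spectrum(CallRecording(x, FS))
        s2 = power_spectrum(CallRecording(x * 7.3, FS))
        np.testing.assert_allclose(s1.level_db, s2.level_db, atol=1e-6)


class TestCepstralSmooth:
    def test_flat_spectrum_unchanged(self):
        grid = np.linspace(0, 22050, 1024)
        flat = PowerSpectrum(grid, np.zeros_like(grid))
        out = cepstral_smooth(flat, 50.0)
        np.testing.assert_allclose(out.level_db, 0.0, atol=1e-9)

    def test_lone_peak_not_shifted(self):
        spec = plant_peak_spectrum([2700.0], widths_hz=120.0)
        out = cepstral_smooth(spec, 50.0)
        assert abs(out.peak_hz - 2700.0) <= 100.0

    def test_small_bandwidth_is_identity_limit(self):
        spec = plant_peak_spectrum([1100.0, 2700.0])
        out = cepstral_smooth(spec, 1e-6)
        assert np.max(np.abs(out.level_db - spec.level_db)) < 0.1

    def test_large_bandwidth_flattens(self):
        spec = plant_peak_spectrum([1100.0, 2700.0])
        out = cepstral_smooth(spec, 1e9)
        assert out.level_db.max() - out.level_db.min() < 1e-6

    def test_removes_fine_ripple_keeps_envelope(self):
        # ripple with a 20 Hz period is finer than the 50 Hz smoothing
        # bandwidth: liftering keeps the broad envelope, erases the ripple
        grid = np.linspace(0, 22050, 4411)
        envelope = -((grid - 3000.0) ** 2) / 2e6
        comb = 6.0 * np.cos(2 * np.pi * grid / 20.0)
        spec = PowerSpectrum(grid, envelope + comb - (envelope + comb).max())
        out = cepstral_smooth(spec, bandwidth_hz=50.0)
        assert abs(out.peak_hz - 3000.0) < 200.0
        # ripple amplitude collapses
        band = (grid > 2500) & (grid < 3500)
        assert np.std(np.diff(out.level_db[band])) < 0.1 * np.std(
            np.diff(spec.level_db[band])
        )

    def test_bad_bandwidth_rejected(self):
        spec = plant_peak_spectrum([1000.0])
        with pytest.raises(ValueError):
            cepstral_smooth(spec, 0.0)


class TestLpcEnvelope:
    def test_two_pole_resonance_recovered(self, rng):
        w0 = 2 * np.pi * 2500 / FS
        r = np.exp(-np.pi * 100 / FS)
        x = ssig.lfilter([1.0], [1.0, -2 * r * np.cos(w0), r**2],
                         rng.standard_normal(2 * FS))
        env = lpc_envelope(CallRecording(x / np.max(np.abs(x)), FS))
        assert env.peak_hz == pytest.approx(2500.0, rel=0.05)

    def test_white_noise_near_flat(self, rng):
        # flat above the pre-emphasis corner region; the first few hundred
        # Hz carry the documented de-tilting boundary artifact
        rec = CallRecording(rng.standard_normal(2 * FS) * 0.3, FS)
        env = lpc_envelope(rec)
        band = env.level_db[env.frequencies_hz >= 500.0]
        assert band.max() - band.min() < 6.0
        assert env.level_db.max() - env.level_db.min() < 20.0

    def test_single_pole_pair_on_pure_tone(self):
        env = lpc_envelope(tone([(2000.0, 1.0)]), n_peaks=1)
        assert env.peak_hz == pytest.approx(2000.0, rel=0.1)
        # one conjugate pole pair -> a single local maximum
        peaks, _ = ssig.find_peaks(env.level_db, prominence=3.0)
        assert len(peaks) == 1

    def test_order_must_be_below_sample_count(self):
        rec = CallRecording(np.sin(np.linspace(0, 100, 1024)), 44100)
        with pytest.raises(ValueError, match="order"):
            lpc_envelope(rec, n_peaks=600)


class TestCentralSegment:
    @pytest.mark.parametrize(
        "start, end, fraction, expected",
        [
            (0.0, 0.2, 0.5, (0.05, 0.15)),
            (1.0, 2.0, 1.0, (1.0, 2.0)),
            (0.0, 0.3, 1 / 3, (0.1, 0.2)),
        ],
    )
    def test_window_arithmetic(self, start, end, fraction, expected):
        got = central_segment(start, end, fraction)
        assert got == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            central_segment(1.0, 1.0)
        with pytest.raises(ValueError):
            central_segment(0.0, 1.0, 0.0)


class TestEstimateFundamental:
    def test_constant_ff_recovered(self):
        rec = synthesize_call(
            CallSpec(ff_contour=((0.0, 2500.0), (0.2, 2500.0)), seed=3)
        )
        ff = estimate_fundamental(rec, central_segment(0, 0.2))
        assert ff == pytest.approx(2500.0, rel=0.01)

    def test_hat_contour_plateau_recovered(self):
        # rising 2.2 -> 2.7 kHz plateau -> falling; the central half is
        # dominated by the plateau
        contour = ((0.0, 2200.0), (0.05, 2700.0), (0.15, 2700.0), (0.2, 2200.0))
        rec = synthesize_call(CallSpec(ff_contour=contour, seed=4))
        ff = estimate_fundamental(rec, central_segment(0, 0.2))
        assert ff == pytest.approx(2700.0, rel=0.02)

    def test_white_noise_gives_no_estimate(self, rng):
        rec = CallRecording(rng.standard_normal(FS) * 0.3, FS)
        assert estimate_fundamental(rec) is None

    @pytest.mark.parametrize("ff", [500.0, 1200.0, 2500.0, 4000.0, 5000.0])
    def test_accuracy_across_band(self, ff):
        """<=1% relative error on noiseless harmonic calls over the
        search band."""
        gains = (0.0, -20.0) if 2 * ff < FS / 2 else (0.0,)
        rec = synthesize_call(
            CallSpec(
                ff_contour=((0.0, ff), (0.3, ff)),
                harmonic_gains_db=gains,
                duration_s=0.3,
                noise_floor_db=-120.0,
                seed=5,
            )
        )
        est = estimate_fundamental(rec, search_hz=(400.0, 6000.0))
        assert est == pytest.approx(ff, rel=0.01)

    def test_bad_search_band_rejected(self):
        rec = synthesize_call(CallSpec(seed=1))
        with pytest.raises(ValueError):
            estimate_fundamental(rec, search_hz=(500.0, 60000.0))


class TestHarmonicAmplitudes:
    def test_planted_gains_recovered(self):
        rec = synthesize_call(
            CallSpec(
                ff_contour=((0.0, 2500.0), (0.2, 2500.0)),
                harmonic_gains_db=(0.0, -20.0, -35.0),
                seed=6,
            )
        )
        prof = harmonic_amplitudes(power_spectrum(rec), 2500.0)
        assert prof.rel_amp_db["FF"] == pytest.approx(0.0, abs=2.0)
        assert prof.rel_amp_db["F2"] == pytest.approx(-20.0, abs=2.0)
        assert prof.rel_amp_db["F3"] == pytest.approx(-35.0, abs=2.0)

    def test_pure_tone_harmonics_at_noise_floor(self):
        rec = synthesize_call(
            CallSpec(
                ff_contour=((0.0, 2500.0), (0.2, 2500.0)),
                harmonic_gains_db=(0.0,),
                noise_floor_db=-70.0,
                seed=7,
            )
        )
        prof = harmonic_amplitudes(power_spectrum(rec), 2500.0)
        assert prof.rel_amp_db["F2"] <= -40.0
        assert prof.rel_amp_db["F3"] <= -40.0

    def test_amplitudes_never_positive(self):
        spec = plant_peak_spectrum([1000.0, 2000.0, 3000.0])
        prof = harmonic_amplitudes(spec, 1000.0)
        assert all(v <= 0.0 for v in prof.rel_amp_db.values())

    def test_nyquist_guard(self):
        spec = plant_peak_spectrum([5000.0])
        with pytest.raises(ValueError, match="exceeds"):
            harmonic_amplitudes(spec, 10000.0)


class TestAverageSpectra:
    def test_identity_on_identical_inputs(self):
        spec = plant_peak_spectrum([2000.0])
        out = average_spectra([spec, spec, spec])
        np.testing.assert_allclose(out.level_db, spec.level_db, atol=1e-9)

    def test_disjoint_peaks_both_present(self):
        s1 = plant_peak_spectrum([2000.0])
        s2 = plant_peak_spectrum([3000.0])
        out = average_spectra([s1, s2])
        peaks = detect_peaks(out)
        # dB-averaging with the other spectrum's tail may shift a peak by
        # a bin or two, but both must survive
        assert len(peaks) == 2
        for want in (2000.0, 3000.0):
            assert min(abs(p - want) for p in peaks) <= 30.0

    def test_order_invariance(self):
        s1 = plant_peak_spectrum([2000.0])
        s2 = plant_peak_spectrum([3000.0], floor_db=-50.0)
        a = average_spectra([s1, s2])
        b = average_spectra([s2, s1])
        np.testing.assert_allclose(a.level_db, b.level_db)

    def test_mismatched_grids_rejected(self):
        s1 = plant_peak_spectrum([2000.0], grid_hz=np.linspace(0, 22050, 100))
        s2 = plant_peak_spectrum([2000.0], grid_hz=np.linspace(0, 22050, 200))
        with pytest.raises(ValueError, match="grid"):
            average_spectra([s1, s2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestDetectPeaks:
    def test_three_planted_lorentzians(self):
        spec = plant_peak_spectrum([1100.0, 2700.0, 5400.0], widths_hz=80.0)
        peaks = detect_peaks(spec)
        bin_w = spec.frequencies_hz[1] - spec.frequencies_hz[0]
        assert len(peaks) == 3
        for got, want in zip(peaks, [1100.0, 2700.0, 5400.0]):
            assert abs(got - want) <= bin_w

    def test_flat_spectrum_empty(self):
        grid = np.linspace(0, 22050, 512)
        assert detect_peaks(PowerSpectrum(grid, np.zeros_like(grid))) == []

    def test_close_peaks_pruned_to_larger(self):
        spec = plant_peak_spectrum(
            [3000.0, 3050.0], widths_hz=15.0, peak_gains_db=[0.0, -3.0],
            grid_hz=np.linspace(0, 22050, 8821),
        )
        peaks = detect_peaks(spec, min_separation_hz=200.0)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(3000.0, abs=10.0)
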