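"""Resampling, filtering, epoching, and STFT featurization."""

import numpy as np
import pytest

from preictal.annotations import ConfigurationError, SeizureEvent, label_periods
from preictal.signal_prep import (
    PrepConfig, Recording, band_for, bandpass, freq_mask, preictal_step,
    resample, segment_epochs, stft_features,
)


def sine_recording(freq_hz, fs, dur_s, amp=1.0, n_ch=1):
    t = np.arange(int(dur_s * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    return Recording(np.tile(sig, (n_ch, 1)), fs, [f"ch{i}" for i in range(n_ch)])


class TestResample:
    def test_sample_count_after_decimation(self):
        rec = sine_recording(10, 1600, 60)
        out = resample(rec, 256)
        assert out.fs == 256 and out.n_samples == 60 * 256

    def test_identity_when_rates_match(self):
        rec = sine_recording(10, 256, 10)
        out = resample(rec, 256)
        np.testing.assert_allclose(out.signal, rec.signal)

    def test_sinusoid_survives_decimation(self):
        rec = sine_recording(10, 1600, 60)
        out = resample(rec, 128)
        x = out.signal[0][128:-128]  # trim filter transients
        # amplitude within 1%, dominant frequency still 10 Hz
        assert np.abs(x).max() == pytest.approx(1.0, rel=0.01)
        spec = np.abs(np.fft.rfft(x))
        assert np.argmax(spec) == pytest.approx(10 * len(x) / 128, abs=1)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            resample(sine_recording(10, 256, 10), 512)


class TestBandpass:
    def test_line_frequency_strongly_attenuated(self):
        # 60 Hz sits 0.26 octave above the 50 Hz edge: a zero-phase 4th-order
        # Butterworth leaves ~2% of its power
        rec = sine_recording(60, 256, 30)
        out = bandpass(rec, 0.5, 50)
        assert np.mean(out.signal**2) <= 0.05 * np.mean(rec.signal**2)

    def test_stopband_twenty_db_one_octave_beyond_edge(self):
        rec = sine_recording(100, 256, 30)  # one octave above 50 Hz
        out = bandpass(rec, 0.5, 50)
        assert np.mean(out.signal**2) <= 0.01 * np.mean(rec.signal**2)

    def test_passband_amplitude_preserved(self):
        rec = sine_recording(10, 256, 30)
        out = bandpass(rec, 0.5, 50)
        mid = out.signal[0][256:-256]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_is_attenuated(self):
        rec = Recording(np.ones((1, 256 * 30)), 256.0, ["c"])
        out = bandpass(rec, 0.5, 50)
        assert np.abs(out.signal[0][256 * 10 : -256]).max() < 0.05

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(sine_recording(10, 128, 10), 0.5, 90)  # above Nyquist

    def test_band_follows_rate(self):
        assert band_for(128) == (0.5, 50.0)
        assert band_for(256) == band_for(512) == (0.5, 90.0)
        assert PrepConfig(128).band == (0.5, 50.0)


class TestPreictalStep:
    def test_step_30_when_target_already_met(self):
        # one lead, L=30: step 30 gives floor(1770/30)+1 = 60 epochs >= 59
        res = preictal_step(30, target_epochs=59)
        assert res.step_s == 30 and res.total_epochs == 60 and res.achieved_target

    def test_one_minute_window_gives_two_epochs_at_step_30(self):
        res = preictal_step(1, target_epochs=1)
        assert res.step_s == 30 and res.total_epochs == 2

    def test_no_overlap_when_target_equals_non_overlapping_count(self):
        res = preictal_step(10, target_epochs=20)  # floor(570/30)+1 = 20
        assert res.step_s == 30 and res.total_epochs == 20

    def test_overlap_grows_to_meet_large_targets(self):
        res = preictal_step(5, target_epochs=120)
        per_lead = int((5 * 60 - 30) / res.step_s) + 1
        assert res.achieved_target and per_lead >= 120 and res.step_s < 30

    def test_unreachable_target_returns_floor_with_flag(self):
        res = preictal_step(1, target_epochs=1000)
        assert res.step_s == 1.0 and not res.achieved_target

    def test_result_approaches_target_from_above(self):
        for target in (40, 77, 200):
            res = preictal_step(10, target_epochs=target)
            if res.achieved_target:
                assert res.total_epochs >= target


class TestSegmentEpochs:
    def make_labeling(self, intervals, dur):
        from preictal.annotations import PeriodLabeling
        return PeriodLabeling(30, dur, intervals)

    def test_counts_in_plain_intervals(self):
        fs = 128
        rec = Recording(np.zeros((1, fs * 400)), float(fs), ["c"])
        lab = self.make_labeling([(0.0, 90.0, "interictal"), (90.0, 400.0, "unused")], 400.0)
        assert segment_epochs(rec, lab, "interictal", 30).data.shape[0] == 3

    def test_interval_shorter_than_epoch_contributes_nothing(self):
        fs = 128
        rec = Recording(np.zeros((1, fs * 100)), float(fs), ["c"])
        lab = self.make_labeling([(0.0, 29.0, "interictal"), (29.0, 100.0, "unused")], 100.0)
        assert segment_epochs(rec, lab, "interictal", 30).data.shape[0] == 0

    def test_overlapping_steps_inside_preictal(self):
        fs = 128
        rec = Recording(np.zeros((1, fs * 400)), float(fs), ["c"])
        lab = self.make_labeling([(0.0, 50.0, "unused"), (50.0, 350.0, "preictal"),
                                  (350.0, 400.0, "unused")], 400.0)
        assert segment_epochs(rec, lab, "preictal", 15).data.shape[0] == 19

    def test_epochs_never_cross_interval_boundaries(self):
        fs = 128
        rec = Recording(np.arange(fs * 200, dtype=float)[None, :] / fs, float(fs), ["c"])
        lab = self.make_labeling([(0.0, 65.0, "interictal"), (65.0, 130.0, "unused"),
                                  (130.0, 200.0, "interictal")], 200.0)
        eps = segment_epochs(rec, lab, "interictal", 30)
        for ep, start in zip(eps.data, eps.start_s):
            assert ep[0, 0] == pytest.approx(start)
            assert start + 30 <= 65.0 + 1e-9 or (130.0 <= start and start + 30 <= 200.0)

    def test_flagged_lead_preictal_skipped(self):
        fs, dur = 128, 8 * 3600.0
        rec = Recording(np.zeros((1, int(fs * dur))), float(fs), ["c"])
        lab = label_periods([SeizureEvent(600.0, 660.0)], 30, dur)
        assert lab.flagged_leads
        assert segment_epochs(rec, lab, "preictal", 30).data.shape[0] == 0


class TestSTFT:
    @pytest.mark.parametrize("fs, F", [(128, 65), (256, 81), (512, 81)])
    def test_shapes_pin_59_frames_and_rate_dependent_bins(self, fs, F, rng):
        x = rng.standard_normal((3, 30 * fs))
        assert stft_features(x, fs).shape == (3, 59, F)

    def test_frame_count_closed_form(self):
        for fs in (128, 256, 512):
            assert (30 * fs - fs) // (fs // 2) + 1 == 59

    def test_all_zero_epoch_hits_log_floor(self):
        out = stft_features(np.zeros((1, 30 * 128)), 128)
        assert np.all(out == 0.0)  # log1p(0)

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            stft_features(np.zeros((1, 29 * 128)), 128)

    def test_bit_identical_determinism(self, rng):
        x = rng.standard_normal((2, 30 * 256))
        a, b = stft_features(x, 256), stft_features(x, 256)
        assert np.array_equal(a, b)

    def test_spectral_energy_monotone_in_variance(self, rng):
        x = rng.standard_normal((1, 30 * 256))
        e1 = np.sum(np.expm1(stft_features(x, 256)) ** 2)
        e2 = np.sum(np.expm1(stft_features(3 * x, 256)) ** 2)
        assert e2 > e1

    def test_pure_tone_lands_in_its_bin(self, rng):
        fs = 256
        t = np.arange(30 * fs) / fs
        x = np.sin(2 * np.pi * 20 * t)[None, :]
        out = stft_features(x, fs)
        bins = freq_mask(fs)
        assert bins[np.argmax(out.mean(axis=1))] == 20


class TestFreqMask:
    def test_bin_counts(self):
        assert freq_mask(128).size == 65
        assert freq_mask(256).size == 81

    def test_line_noise_band_excluded_at_high_rates(self):
        for fs in (256, 512):
            bins = freq_mask(fs)
            assert not np.any((bins >= 55) & (bins <= 64))
            # 1 Hz spacing everywhere except the single 54 -> 65 jump
            diffs = np.diff(bins)
            assert np.sum(diffs == 11) == 1 and np.sum(diffs == 1) == diffs.size - 1

    def test_512_and_256_keep_identical_hz_lists(self):
        assert np.array_equal(freq_mask(512), freq_mask(256))

    def test_128_keeps_full_one_sided_spectrum(self):
        assert np.array_equal(freq_mask(128), np.arange(65))

    def test_unsupported_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            freq_mask(200)
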