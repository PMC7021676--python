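"""Detector behaviour: filter spec, F-test calibration, mask combination,
component extraction, harmonic suppression."""

import numpy as np
import pytest

from squeaktrace import (
    ArenaConfig,
    SegmentationParams,
    VocalEvent,
    bandpass_filter,
    combine_and_smooth,
    extract_signals,
    multitaper_ftest_mask,
    segment_audio,
    synthesize_audio,
)
from squeaktrace.segmentation import CombinedMask, TFMask

FS = 250_000.0
PARAMS = SegmentationParams()


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(int(0.05 * FS)) / FS
        x = np.sin(2 * np.pi * 60e3 * t)
        y = bandpass_filter(x, FS)
        assert abs(20 * np.log10(_rms(y) / _rms(x))) < 1.0

    def test_out_of_band_tone_attenuated_40db(self):
        t = np.arange(int(0.05 * FS)) / FS
        x = np.sin(2 * np.pi * 10e3 * t)
        y = bandpass_filter(x, FS)
        assert 20 * np.log10(_rms(y) / _rms(x)) < -40.0

    def test_silence_maps_to_silence(self):
        y = bandpass_filter(np.zeros(4096), FS)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(1024), 200_000.0)


class TestFtestMask:
    def test_type_one_rate_on_noise(self):
        """Per-pixel false-alarm rate on bandpassed white noise sits near
        the nominal alpha = 0.05."""
        fracs = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(100_000)
            x = bandpass_filter(x, FS)
            m = multitaper_ftest_mask(x, FS, PARAMS, 64)
            fracs.append(m.mask.mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_strong_tone_detected_in_nearly_all_windows(self):
        nfft = 64
        f_bin = 15 * FS / nfft  # exact bin centre, ~58.6 kHz
        t = np.arange(200_000) / FS
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * f_bin * t) + 0.01 * rng.standard_normal(t.size)
        m = multitaper_ftest_mask(x, FS, PARAMS, nfft)
        row = int(np.argmin(np.abs(m.freqs - f_bin)))
        assert m.mask[row].mean() > 0.95

    def test_all_zero_input_gives_zero_mask(self):
        m = multitaper_ftest_mask(np.zeros(10_000), FS, PARAMS, 64)
        assert not m.mask.any()

    def test_short_signal_gives_empty_mask(self):
        m = multitaper_ftest_mask(np.zeros(32), FS, PARAMS, 64)
        assert m.mask.shape[1] == 0

    def test_lower_alpha_never_adds_pixels(self):
        x = np.random.default_rng(3).standard_normal(60_000)
        x = bandpass_filter(x, FS)
        counts = []
        for alpha in (0.05, 0.01, 0.001):
            p = SegmentationParams(ftest_alpha=alpha)
            counts.append(multitaper_ftest_mask(x, FS, p, 64).mask.sum())
        assert counts[0] >= counts[1] >= counts[2]


def _delta_mask(row, col, shape=(40, 200), nfft=64):
    mask = np.zeros(shape, bool)
    mask[row, col] = True
    freqs = 30e3 + np.arange(shape[0]) * 2e3
    times = (np.arange(shape[1]) * (nfft // 2) + nfft / 2) / FS
    return TFMask(mask, freqs, times, nfft, nfft // 2)


class TestCombineAndSmooth:
    def test_delta_dilates_to_exact_box_support(self):
        """A single pixel present on every channel grows to exactly the
        11 x 15 = 165-pixel box."""
        masks = [[_delta_mask(20, 100) for _ in range(8)]]
        out = combine_and_smooth(masks, PARAMS)
        assert out.raw.sum() == 1
        assert out.dilated.sum() == 11 * 15

    def test_all_zero_masks_stay_zero(self):
        zero = _delta_mask(0, 0)
        zero.mask[:] = False
        out = combine_and_smooth([[zero] * 8], PARAMS)
        assert not out.dilated.any()

    def test_minority_channel_detection_suppressed(self):
        active = _delta_mask(20, 100)
        silent = _delta_mask(20, 100)
        silent.mask[:] = False
        masks = [[active] * 4 + [silent] * 4]  # 4 of 8 < min_channels
        out = combine_and_smooth(masks, PARAMS)
        assert not out.raw.any()

    def test_gap_merging_follows_box_geometry(self):
        near = [
            [
                TFMask(
                    _delta_mask(20, 100).mask | _delta_mask(20, 110).mask,
                    _delta_mask(20, 100).freqs, _delta_mask(20, 100).times, 64, 32,
                )
            ]
            * 8
        ]
        far = [
            [
                TFMask(
                    _delta_mask(20, 100).mask | _delta_mask(20, 160).mask,
                    _delta_mask(20, 100).freqs, _delta_mask(20, 100).times, 64, 32,
                )
            ]
            * 8
        ]
        from scipy import ndimage

        merged = combine_and_smooth(near, PARAMS)
        assert ndimage.label(merged.dilated)[1] == 1
        split = combine_and_smooth(far, PARAMS)
        assert ndimage.label(split.dilated)[1] == 2

    def test_empty_mask_set_rejected(self):
        with pytest.raises(ValueError):
            combine_and_smooth([], PARAMS)


def _combined_from_raw(raw, dt=64 / 2 / FS):
    freqs = 30e3 + np.arange(raw.shape[0]) * 2e3
    times = np.arange(raw.shape[1]) * dt + dt
    return CombinedMask(raw=raw, dilated=raw, freqs=freqs, times=times)


class TestExtractSignals:
    def test_pixel_threshold_boundary(self):
        """A 1499-pixel component is discarded; 1500 is kept."""
        raw = np.zeros((50, 400), bool)
        raw[10:60, 50:80] = True  # 50 rows max is 50 -> use explicit size
        raw = np.zeros((60, 400), bool)
        raw[5:55, 50:80] = True  # 50 x 30 = 1500
        combined = _combined_from_raw(raw)
        assert len(extract_signals(combined, None, PARAMS)) == 1
        raw2 = raw.copy()
        raw2[5, 50] = False  # 1499
        assert len(extract_signals(_combined_from_raw(raw2), None, PARAMS)) == 0

    def test_empty_mask_gives_empty_list(self):
        combined = _combined_from_raw(np.zeros((40, 100), bool))
        assert extract_signals(combined, None, PARAMS) == []

    def test_harmonic_component_suppressed(self):
        raw = np.zeros((80, 400), bool)
        raw[10:21, 50:187] = True  # fundamental: centroid 45 kHz, 1507 px
        raw[55:66, 50:187] = True  # harmonic band: centroid 90 kHz = 2.0x
        freqs = np.linspace(30e3, 109e3, 80)  # 1 kHz rows: row r -> 30 + r kHz
        combined = CombinedMask(raw=raw, dilated=raw, freqs=freqs,
                                times=np.arange(400) * 1.28e-4 + 1e-4)
        sigs = extract_signals(combined, None, PARAMS)
        assert len(sigs) == 1
        assert sigs[0].contour[:, 1].mean() < 60e3

    def test_end_to_end_chirp_detection(self):
        """A 50 ms 60->80 kHz chirp at 20 dB SNR yields exactly one signal
        bracketing the true times within one coarse time bin."""
        arena = ArenaConfig(duration=0.6)
        contour = np.column_stack([np.linspace(0, 0.05, 5), np.linspace(60e3, 80e3, 5)])
        ev = VocalEvent(time=0.25, vocalizer=1, source_xy=np.array([38.0, 38.0]),
                        contour=contour)
        audio = synthesize_audio([ev], arena, snr_db=20, seed=4, duration=0.6)
        sigs = segment_audio(audio)
        assert len(sigs) == 1
        coarse_bin = 256 / 2 / FS  # hop of the coarsest raster
        prop = 38.0 / 34300.0  # propagation delay to the nearest mics
        assert abs(sigs[0].start_time - (0.25 + prop)) <= coarse_bin + prop
        assert abs(sigs[0].stop_time - (0.30 + prop)) <= coarse_bin + prop
        f = sigs[0].contour[:, 1]
        assert 55e3 < f.min() < 65e3 and 75e3 < f.max() < 85e3
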