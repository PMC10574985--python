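"""Preprocessing chain: window arithmetic, spectral behaviour of the
filters, blink suppression against a paired clean signal, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fatiguekit as fk
from fatiguekit.preprocess import (EpochPreprocessor, bandpass_butterworth,
                                   minmax01, notch_50, remove_blinks,
                                   select_middle_window)
from fatiguekit.synth import blink_template

FS = 250.0


def tone(freq, n=3750, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


def tone_power_db(x, freq, fs=FS):
    spec = np.fft.rfft(x * np.hanning(len(x)))
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return 10 * np.log10(np.abs(spec[np.argmin(np.abs(freqs - freq))]) ** 2)


class TestMiddleWindow:
    def test_center_window_indices(self):
        rec = fk.generate_recording(0, 300, seed=0)
        win = select_middle_window(rec, 15)
        start = int((300 - 15) / 2 * 250)
        assert win["O1"].shape == (3750,)
        assert np.array_equal(win["O1"], rec.channels["O1"][start: start + 3750])

    def test_window_equal_to_recording_is_identity(self):
        rec = fk.generate_recording(0, 15, seed=0)
        win = select_middle_window(rec, 15)
        assert np.array_equal(win["O1"], rec.channels["O1"])

    def test_too_short_recording_raises(self):
        rec = fk.generate_recording(0, 10, seed=0)
        with pytest.raises(ValueError):
            select_middle_window(rec, 15)


class TestNotch:
    def test_50hz_tone_attenuated_20db(self):
        x = tone(50)
        drop = tone_power_db(x, 50) - tone_power_db(notch_50(x), 50)
        assert drop >= 20

    def test_10hz_tone_preserved_within_1db(self):
        x = tone(10)
        drop = tone_power_db(x, 10) - tone_power_db(notch_50(x), 10)
        assert abs(drop) < 1

    def test_zero_signal_unchanged(self):
        assert np.allclose(notch_50(np.zeros(1000)), 0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            notch_50(np.ones(100), fs=100)


class TestBandpass:
    def test_midband_preserved_within_3db(self):
        x = tone(10)
        drop = tone_power_db(x, 10) - tone_power_db(bandpass_butterworth(x), 10)
        assert abs(drop) < 3

    def test_100hz_attenuated_more_than_10hz(self):
        y10 = bandpass_butterworth(tone(10))
        y100 = bandpass_butterworth(tone(100))
        assert (tone_power_db(y100, 100) - tone_power_db(tone(100), 100)
                < tone_power_db(y10, 10) - tone_power_db(tone(10), 10))

    @pytest.mark.parametrize("band", [(0, 60), (60, 0.05), (0.05, 200)])
    def test_invalid_band_rejected(self, band):
        with pytest.raises(ValueError):
            bandpass_butterworth(np.ones(500), low=band[0], high=band[1])

    def test_filters_are_linear(self):
        """Scaling the input scales the (pre-normalization) output."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        for f in (notch_50, bandpass_butterworth):
            assert np.allclose(f(3.7 * x), 3.7 * f(x))


class TestRemoveBlinks:
    def _controlled_epoch(self):
        rng = np.random.default_rng(4)
        t = np.arange(3750) / FS
        background = 8 * np.sin(2 * np.pi * 10 * t) + 2 * rng.standard_normal(3750)
        tmpl = blink_template(FS) * 90
        blink = np.zeros(3750)
        blink[1200: 1200 + len(tmpl)] = tmpl
        return background, blink, slice(1200, 1200 + len(tmpl))

    def test_blink_peak_reduced_80_percent(self):
        background, blink, win = self._controlled_epoch()
        dirty = background + blink
        out = remove_blinks(np.stack([dirty, background * 0.8]),
                            ("Fp1", "O1"))
        assert np.abs(out[0][win]).max() < 0.2 * np.abs(dirty[win]).max()

    def test_blink_free_epoch_untouched(self):
        background, _, _ = self._controlled_epoch()
        arr = np.stack([background, background * 0.8])
        out = remove_blinks(arr, ("Fp1", "O1"))
        rms = np.sqrt(np.mean((out - arr) ** 2))
        assert rms <= 0.05 * np.sqrt(np.mean(arr ** 2))

    def test_all_zero_epoch_unchanged(self):
        arr = np.zeros((2, 1000))
        assert np.array_equal(remove_blinks(arr, ("Fp1", "O1")), arr)

    def test_missing_frontal_channel_raises(self):
        with pytest.raises(ValueError, match="frontal"):
            remove_blinks(np.zeros((2, 100)), ("O1", "O2"))


class TestMinMax:
    def test_closed_form(self):
        assert np.allclose(minmax01(np.array([-1.0, 0.0, 1.0])),
                           [0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros(self):
        assert np.array_equal(minmax01(np.full(10, 3.3)), np.zeros(10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax01(np.array([]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50)
           .filter(lambda v: max(v) > min(v)))
    @settings(derandomize=True, max_examples=50)
    def test_bounds_and_idempotence(self, values):
        x = np.array(values)
        y = minmax01(x)
        assert y.min() == 0.0 and y.max() == 1.0
        assert np.allclose(minmax01(y), y)


class TestPipeline:
    def test_output_in_unit_interval_with_full_provenance(self, small_recordings):
        ep = fk.preprocess_pipeline(small_recordings.recordings[0])
        assert ep.data.shape == (4, 3750)
        assert ep.data.min() >= 0.0 and ep.data.max() <= 1.0
        assert ep.provenance == ("middle_window", "notch",
                                 "bandpass_butterworth", "remove_blinks",
                                 "minmax01")

    def test_pipeline_is_deterministic(self, small_recordings):
        rec = small_recordings.recordings[3]
        e1 = fk.preprocess_pipeline(rec)
        e2 = fk.preprocess_pipeline(rec)
        assert np.array_equal(e1.data, e2.data)

    def test_short_recording_raises_from_window_stage(self):
        rec = fk.generate_recording(0, 10, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            fk.preprocess_pipeline(rec)

    def test_transform_matches_per_recording_path(self, small_recordings):
        pre = EpochPreprocessor()
        ds = pre.transform(small_recordings)
        ep0 = pre.transform_recording(small_recordings.recordings[0])
        assert np.array_equal(ds.epochs[0], ep0.data)
        assert np.array_equal(ds.labels, small_recordings.labels)
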