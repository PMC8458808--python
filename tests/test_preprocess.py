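"""Filtering, normalization, epoching, and temperature assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from thermoeeg import (
    DegenerateSignalError,
    EpochRecord,
    FilterConfigError,
    SessionRecording,
    TemperatureProfile,
    assign_temperature,
    bandpass_filter,
    make_epochs,
    normalize_01,
    round_half_up,
)

FS = 1000.0


def _tone(freq, duration=5.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass_filter(np.full(5000, 0.7), FS)
        # ignore the edge transient of the high-pass
        assert np.max(np.abs(out[1000:-1000])) < 1e-3

    def test_midband_tone_preserved(self):
        # oracle: the filter's own magnitude response at 10 Hz
        sos = sps.butter(4, [1.0, 50.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10.0], fs=FS)
        expected = np.abs(h[0]) ** 2  # forward-backward squares the response
        out = bandpass_filter(_tone(10.0, 10.0), FS)
        amp = np.max(np.abs(out[2000:-2000]))
        assert amp == pytest.approx(expected, abs=0.05)
        assert 0.95 <= amp <= 1.05

    def test_stopband_tone_attenuated(self):
        out = bandpass_filter(_tone(100.0), FS)
        assert np.max(np.abs(out[1000:-1000])) < 0.1

    def test_nyquist_violation_rejected(self):
        with pytest.raises(FilterConfigError):
            bandpass_filter(np.zeros(1000), sampling_rate=90.0, high=50.0)

    def test_linearity(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        lhs = bandpass_filter(2.5 * x - 1.5 * y, FS)
        rhs = 2.5 * bandpass_filter(x, FS) - 1.5 * bandpass_filter(y, FS)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_zero_phase_no_lag(self):
        x = _tone(8.0, 10.0)
        y = bandpass_filter(x, FS)
        mid = slice(2000, 8000)
        lags = sps.correlation_lags(len(x[mid]), len(y[mid]))
        xc = sps.correlate(x[mid], y[mid])
        assert lags[np.argmax(xc)] == 0


class TestNormalize:
    def test_affine_map(self):
        assert np.allclose(normalize_01(np.array([-2.0, 0.0, 2.0])),
                           [0.0, 0.5, 1.0])

    def test_unit_range_unchanged(self):
        x = np.array([0.0, 0.25, 1.0])
        assert np.allclose(normalize_01(x), x)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalize_01(np.full(10, 3.3))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, unique=True))
    def test_output_spans_unit_interval(self, values):
        out = normalize_01(np.array(values))
        assert out.min() == 0.0
        assert out.max() == 1.0


class TestRounding:
    @pytest.mark.parametrize("temp,expected,kept", [
        (41.5, 42, True),    # half rounds up
        (36.4, 36, False),   # below range after rounding -> discarded
        (36.6, 37, True),    # rounds into range -> kept
        (39.2, 39, True),
        (42.5, 43, False),
        (42.49, 42, True),
    ])
    def test_half_up_and_discard_rule(self, temp, expected, kept):
        e = EpochRecord("s", 0, 0.0, np.zeros(4), mean_temp=temp)
        e = assign_temperature(e)
        assert e.rounded_temp == expected
        assert e.kept is kept

    @given(st.floats(30.0, 50.0))
    def test_round_half_up_is_nearest_with_up_ties(self, x):
        r = round_half_up(x)
        assert abs(r - x) <= 0.5
        if abs(x - (np.floor(x) + 0.5)) < 1e-12:
            assert r == int(np.floor(x)) + 1


def _flat_recording(duration_s, fs=100.0, temp=39.0):
    n = int(duration_s * fs)
    times = np.arange(int(duration_s) + 1, dtype=float)
    profile = TemperatureProfile(
        times=times, temps=np.full(times.size, temp),
        phase=np.full(times.size, "unknown"),
    )
    rng = np.random.default_rng(0)
    return SessionRecording(rng.standard_normal(n), fs, profile, "flat")


class TestEpoching:
    def test_1500s_session_yields_300_epochs(self, default_session):
        epochs = make_epochs(default_session)
        assert len(epochs) == 300

    def test_trailing_partial_epoch_dropped(self):
        epochs = make_epochs(_flat_recording(12.0))
        assert len(epochs) == 2

    def test_start_times_are_multiples_of_epoch_length(self):
        epochs = make_epochs(_flat_recording(18.0))
        assert [e.start_time for e in epochs] == [0.0, 5.0, 10.0]

    def test_short_recording_gives_empty_list(self):
        assert make_epochs(_flat_recording(3.0)) == []

    def test_epochs_tile_the_signal_without_overlap(self, short_session):
        epochs = make_epochs(short_session)
        spe = int(5.0 * short_session.sampling_rate)
        reassembled = np.concatenate([e.samples for e in epochs])
        assert np.array_equal(reassembled,
                              short_session.eeg[: len(epochs) * spe])

    def test_kept_epochs_only_in_range(self, short_session):
        for e in make_epochs(short_session):
            if e.kept:
                assert 37 <= e.rounded_temp <= 42
            else:
                assert e.rounded_temp < 37 or e.rounded_temp > 42

    def test_mean_temp_matches_profile(self, short_session):
        epochs = make_epochs(short_session)
        # baseline epochs sit at 37 °C exactly
        assert epochs[0].mean_temp == pytest.approx(37.0)
        # epochs in the hold phase sit at 42 °C: protocol is 60 s baseline,
        # 120 s ramp, 60 s hold
        hold = [e for e in epochs if 185.0 <= e.start_time < 235.0]
        assert all(e.mean_temp == pytest.approx(42.0) for e in hold)
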