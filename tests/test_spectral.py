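"""Welch spectra, band integration, and band-power normalization."""

import numpy as np
import pandas as pd
import pytest

from thermoeeg import (
    BandDefinition,
    BandError,
    DEFAULT_BANDS,
    EpochRecord,
    band_power,
    band_powers_by_epoch,
    epoch_power_spectrum,
    normalize_band_powers,
    summarize_bands_session,
)

FS = 250.0


def _epoch(samples, temp=37, session="s", idx=0):
    e = EpochRecord(session, idx, 0.0, np.asarray(samples, float),
                    mean_temp=float(temp))
    e.rounded_temp = int(temp)
    e.kept = True
    return e


class TestPowerSpectrum:
    def test_zero_signal_zero_spectrum(self):
        freqs, psd = epoch_power_spectrum(np.zeros(int(5 * FS)), FS)
        assert np.all(psd == 0.0)
        assert freqs[1] - freqs[0] == pytest.approx(0.5)

    def test_theta_tone_lands_in_theta(self):
        t = np.arange(int(5 * FS)) / FS
        freqs, psd = epoch_power_spectrum(np.sin(2 * np.pi * 6.0 * t), FS)
        total = band_power(freqs, psd, BandDefinition("all", 1.0, 30.0))
        theta = band_power(freqs, psd, DEFAULT_BANDS[1])
        assert theta / total >= 0.90

    def test_parseval_on_white_noise(self, rng):
        # integral of the PSD over [0, Nyquist] approximates the variance
        ratios = []
        for _ in range(100):
            x = rng.standard_normal(int(5 * FS))
            freqs, psd = epoch_power_spectrum(x, FS)
            ratios.append(np.trapezoid(psd, freqs) / np.var(x))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)

    def test_epoch_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            epoch_power_spectrum(np.zeros(int(FS)), FS)


class TestBandPower:
    def test_flat_psd_rectangle_area(self):
        freqs = np.arange(0, 40.5, 0.5)
        psd = np.ones_like(freqs)
        assert band_power(freqs, psd, DEFAULT_BANDS[0]) == pytest.approx(3.0)

    def test_bands_partition_total_power(self, rng):
        x = rng.standard_normal(int(5 * FS))
        freqs, psd = epoch_power_spectrum(x, FS)
        total = band_power(freqs, psd, BandDefinition("all", 1.0, 30.0))
        parts = sum(band_power(freqs, psd, b) for b in DEFAULT_BANDS)
        assert parts == pytest.approx(total, rel=1e-10)

    def test_white_noise_band_power_scales_with_bandwidth(self, rng):
        # E[beta power] / E[delta power] = 18 Hz / 3 Hz for white noise
        ratios = []
        for _ in range(100):
            x = rng.standard_normal(int(5 * FS))
            freqs, psd = epoch_power_spectrum(x, FS)
            ratios.append(band_power(freqs, psd, DEFAULT_BANDS[3])
                          / band_power(freqs, psd, DEFAULT_BANDS[0]))
        assert np.mean(ratios) == pytest.approx(6.0, rel=0.20)

    def test_empty_band_rejected(self):
        with pytest.raises(BandError):
            BandDefinition("bad", 8.0, 8.0)

    def test_band_outside_grid_rejected(self):
        freqs = np.arange(0, 20.5, 0.5)
        with pytest.raises(BandError):
            band_power(freqs, np.ones_like(freqs), BandDefinition("hi", 12, 30))


class TestNormalization:
    def test_two_epoch_minmax(self):
        out = normalize_band_powers(pd.DataFrame({"delta": [2.0, 4.0]}))
        assert list(out["delta"]) == [0.0, 1.0]

    def test_zero_range_maps_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_band_powers(pd.DataFrame({"delta": [3.0, 3.0]}))
        assert np.all(out["delta"] == 0.0)
        assert any("zero power range" in r.message for r in caplog.records)

    def test_monotone_map_preserves_order(self):
        raw = pd.DataFrame({"theta": np.linspace(10.0, 1.0, 20)})
        out = normalize_band_powers(raw)
        assert np.all(np.diff(out["theta"]) < 0)
        assert out["theta"].iloc[0] == 1.0
        assert out["theta"].iloc[-1] == 0.0

    def test_scale_invariance_of_normalized_summaries(self, rng):
        # multiplying a session's raw signal by c > 0 scales every epoch's
        # band power by c^2 and leaves min-max normalized values unchanged
        epochs = [
            _epoch(rng.standard_normal(int(5 * FS)), temp=37 + (i % 3), idx=i)
            for i in range(6)
        ]
        raw = band_powers_by_epoch(epochs, FS)
        scaled = [_epoch(3.7 * e.samples, e.rounded_temp, idx=e.epoch_index)
                  for e in epochs]
        raw_scaled = band_powers_by_epoch(scaled, FS)
        a = normalize_band_powers(raw)
        b = normalize_band_powers(raw_scaled)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestBandSummaries:
    def test_session_summary_single_temperature(self, rng):
        epochs = [_epoch(rng.standard_normal(int(5 * FS)), 40, idx=i)
                  for i in range(4)]
        norm = normalize_band_powers(band_powers_by_epoch(epochs, FS))
        s = summarize_bands_session(norm, epochs)
        assert s.mean_at("delta", 40) == pytest.approx(
            float(norm["delta"].mean())
        )
        assert set(s.table.index.get_level_values(1)) == {40}

    def test_endpoints_attained_per_band(self, rng):
        epochs = [_epoch(rng.standard_normal(int(5 * FS)), 37 + (i % 6), idx=i)
                  for i in range(12)]
        norm = normalize_band_powers(band_powers_by_epoch(epochs, FS))
        for band in norm.columns:
            assert norm[band].min() == 0.0
            assert norm[band].max() == 1.0
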