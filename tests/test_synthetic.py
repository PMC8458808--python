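"""Protocol construction and synthetic-session generation."""

import numpy as np
import pytest
from scipy import stats as spstats

from thermoeeg import (
    CALIBRATED_GENERATOR,
    GeneratorError,
    ProtocolConfig,
    ProtocolError,
    make_temperature_profile,
    synthesize_eeg,
)
from thermoeeg.preprocess import make_epochs, bandpass_filter, normalize_01
from thermoeeg.amplitude import max_peak_to_peak


class TestProtocol:
    def test_default_session_lasts_25_minutes(self):
        cfg = ProtocolConfig()
        assert cfg.total_duration == pytest.approx(1500.0)
        profile = make_temperature_profile(cfg)
        assert profile.duration == pytest.approx(1500.0)

    def test_phase_durations_match_closed_forms(self):
        cfg = ProtocolConfig()
        profile = make_temperature_profile(cfg)
        # 0.5 °C/min over 5 °C -> 600 s of ramp; 1 °C/min cooldown -> 300 s
        counts = {p: int(np.sum(profile.phase == p))
                  for p in ("baseline", "ramp", "hold", "cooldown")}
        assert counts["baseline"] == 300
        assert counts["ramp"] == 600
        assert counts["hold"] == 300
        # cooldown keeps the final boundary sample
        assert counts["cooldown"] == 301

    def test_temperatures_bounded_and_piecewise_linear(self):
        profile = make_temperature_profile()
        assert profile.temps.min() == pytest.approx(37.0)
        assert profile.temps.max() == pytest.approx(42.0)
        ramp = profile.temps[profile.phase == "ramp"]
        assert np.allclose(np.diff(ramp), 0.5 / 60.0)

    def test_symmetric_profile_without_plateaus(self):
        cfg = ProtocolConfig(baseline_duration=0.0, hold_duration=0.0,
                             ramp_rate=1.0, cooldown_rate=1.0)
        profile = make_temperature_profile(cfg)
        assert np.allclose(profile.temps, profile.temps[::-1])

    @pytest.mark.parametrize("kwargs", [
        {"ramp_rate": 0.0},
        {"cooldown_rate": -1.0},
        {"peak_temp": 36.0},
        {"baseline_duration": -5.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ProtocolError):
            ProtocolConfig(**kwargs)


class TestGenerator:
    def test_zero_gains_give_zero_signal(self, short_protocol):
        gen = CALIBRATED_GENERATOR.replace(
            band_gains={b: 0.0 for b in ("delta", "theta", "alpha", "beta")},
            noise_gain=0.0, sampling_rate=500.0, seed=3,
        )
        rec = synthesize_eeg(make_temperature_profile(short_protocol), gen)
        assert np.all(rec.eeg == 0.0)

    def test_same_seed_bit_identical(self, short_protocol):
        profile = make_temperature_profile(short_protocol)
        gen = CALIBRATED_GENERATOR.replace(sampling_rate=500.0, seed=11)
        a = synthesize_eeg(profile, gen).eeg
        b = synthesize_eeg(profile, gen).eeg
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self, short_protocol):
        profile = make_temperature_profile(short_protocol)
        a = synthesize_eeg(profile, CALIBRATED_GENERATOR.replace(seed=1)).eeg
        b = synthesize_eeg(profile, CALIBRATED_GENERATOR.replace(seed=2)).eeg
        assert not np.array_equal(a, b)

    def test_sample_count_matches_duration(self, short_session, short_protocol):
        expected = round(short_protocol.total_duration * short_session.sampling_rate)
        assert short_session.eeg.size == expected

    def test_nonpositive_envelope_rejected(self, short_protocol):
        gen = CALIBRATED_GENERATOR.replace(
            envelope_intercept=1.0, envelope_slope=-0.05  # E(42) < 0
        )
        with pytest.raises(GeneratorError):
            synthesize_eeg(make_temperature_profile(short_protocol), gen)

    def test_hold_rms_tracks_envelope_ratio(self):
        # with no transients/suppression/jitter, RMS(42 °C hold)/RMS(baseline)
        # should match the closed-form envelope x band-slope attenuation
        gen = CALIBRATED_GENERATOR.replace(
            sampling_rate=500.0, seed=5, session_jitter_sd=0.0,
            transient_rate=0.0, suppression_rate=0.0,
        )
        cfg = ProtocolConfig(baseline_duration=120.0, ramp_rate=2.5,
                             hold_duration=120.0, cooldown_rate=5.0)
        profile = make_temperature_profile(cfg)
        rec = synthesize_eeg(profile, gen)
        t = rec.times
        base = rec.eeg[t < 120.0]
        hold = rec.eeg[(t >= 120.0 + 120.0) & (t < 240.0 + 120.0)]
        observed = np.sqrt(np.mean(hold**2)) / np.sqrt(np.mean(base**2))

        e_ratio = gen.envelope(42.0) / gen.envelope(37.0)
        num = sum(
            (gen.band_gains[b] * (1 + 5 * gen.per_band_slopes[b])) ** 2
            for b in gen.band_gains
        ) + gen.noise_gain**2
        den = sum(g**2 for g in gen.band_gains.values()) + gen.noise_gain**2
        expected = e_ratio * np.sqrt(num / den)
        assert observed == pytest.approx(expected, rel=0.15)

    def test_epoch_rms_declines_with_temperature(self):
        """Monotone envelope: per-temperature epoch RMS decreases with
        temperature (negative Spearman correlation) across sessions."""
        profile = make_temperature_profile(
            ProtocolConfig(baseline_duration=60.0, ramp_rate=2.5,
                           hold_duration=60.0, cooldown_rate=5.0)
        )
        temps_all, rms_all = [], []
        zero_slopes = {b: 0.0 for b in ("delta", "theta", "alpha", "beta")}
        for seed in range(8):
            gen = CALIBRATED_GENERATOR.replace(sampling_rate=500.0, seed=seed,
                                               per_band_slopes=zero_slopes)
            rec = synthesize_eeg(profile, gen)
            # RMS on the filtered trace (normalization adds a 0.5 offset that
            # would mask the amplitude trend)
            sig = bandpass_filter(rec.eeg, rec.sampling_rate)
            for e in make_epochs(rec, signal=sig):
                if e.kept:
                    temps_all.append(e.rounded_temp)
                    rms_all.append(float(np.sqrt(np.mean(e.samples**2))))
        rho, p = spstats.spearmanr(temps_all, rms_all)
        assert rho < 0
        assert p < 0.01

    def test_amplitude_declines_with_temperature(self, default_session):
        sig = normalize_01(
            bandpass_filter(default_session.eeg, default_session.sampling_rate)
        )
        epochs = [e for e in make_epochs(default_session, signal=sig) if e.kept]
        temps = [e.rounded_temp for e in epochs]
        amps = [max_peak_to_peak(e) for e in epochs]
        rho, p = spstats.spearmanr(temps, amps)
        assert rho < 0
        assert p < 0.01


class TestCalibration:
    def test_fixed_point_returns_config_unchanged(self):
        from thermoeeg import calibrate_generator, evaluate_generator
        gen = CALIBRATED_GENERATOR.replace(sampling_rate=500.0)
        targets = evaluate_generator(gen, 2, seed=900)
        out = calibrate_generator(
            {k: targets[k] for k in
             ("amplitude_37", "amplitude_42", "delta_42", "theta_42")},
            n_sessions=2, seed=900, base_config=gen,
        )
        assert out == gen

    def test_negative_target_rejected(self):
        from thermoeeg import CalibrationError, calibrate_generator
        with pytest.raises(CalibrationError, match="positive"):
            calibrate_generator({"amplitude_37": -1.0, "amplitude_42": 0.3},
                                n_sessions=1, seed=0)

    def test_non_monotone_targets_rejected(self):
        from thermoeeg import CalibrationError, calibrate_generator
        with pytest.raises(CalibrationError, match="monotone"):
            calibrate_generator({"amplitude_37": 0.3, "amplitude_42": 0.4},
                                n_sessions=1, seed=0)
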