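# Methods

## The study design being emulated

Each session records one differential cortical EEG channel from an
anesthetized mouse while core (rectal) temperature follows a fixed protocol:
5 min at 37 °C (baseline), a continuous ramp at 0.5 °C/min to 42 °C (10 min),
5 min of hold at 42 °C, and a cool-down back to 37 °C. The cool-down rate is
not part of the protocol definition; we take 1.0 °C/min, which closes the
session at exactly 25 min. A study comprises 19 such sessions. The
temperature channel is emitted at 1 Hz and linearly interpolated onto the
EEG time axis (constant extrapolation for at most one epoch at the edges).

## Analysis pipeline

1. **Conditioning.** Zero-phase bandpass 1–50 Hz (4th-order Butterworth,
   applied forward–backward via `scipy.signal.sosfiltfilt`, which squares the
   magnitude response and cancels phase; default odd-reflection padding).
   The filtered trace is min–max normalized to [0, 1] over the whole session.
2. **Epoching.** Contiguous, non-overlapping 5-s epochs from t = 0; a
   trailing partial epoch is dropped. Each epoch's mean temperature is
   rounded half-up to the nearest integer °C; epochs whose rounded value
   falls outside 37–42 °C are discarded. The discard rule operates on the
   rounded value (36.6 °C → 37, kept; 36.4 °C → 36, discarded); whether the
   original analysis rounded before or after discarding is ambiguous, and
   this is our reading.
3. **Amplitude.** Per kept epoch, the maximum peak-to-peak amplitude
   `max − min` of the normalized samples. Mean, sample SD (n−1 denominator;
   undefined at n = 1 rather than 0) and n per temperature, per session;
   study-level summaries average the session means with equal weight.
   Percent reduction relative to 37 °C is computed two ways — on the study
   means, and per session then averaged — because the two orders of
   averaging differ in general; both are reported and labeled.
4. **Regression.** Unweighted OLS of the six per-temperature study means on
   temperature (slope in normalized units per °C, intercept, R²). The fit
   uses per-temperature means, not raw epochs.
5. **Band power.** Per kept epoch, Welch PSD with 2-s Hann segments and 50%
   overlap (0.5 Hz resolution, 4 segments per epoch; no detrending —
   conditioning already removed DC). Band powers are trapezoidal integrals
   over delta [1, 4), theta [4, 8), alpha [8, 12), beta [12, 30) Hz; edges
   are half-open so adjacent bands share no content, and numerically the
   trapezoid rule on the closed grid interval makes the four bands tile the
   total 1–30 Hz power exactly. Each band is min–max normalized across the
   session's kept epochs (the only normalization scope that yields mid-scale
   means rather than values pinned near 1 for the dominant delta band), then
   summarized per temperature and across sessions. Integration precedes
   normalization.
6. **Inference.** Two-sample permutation test on |mean(a) − mean(b)|,
   two-sided. Monte-Carlo backend: 20,000 label permutations sampled with
   replacement, seeded, `p = (b + 1)/(m + 1)` with ties counted toward b —
   never anti-conservative and never exactly 0 (minimum reportable p at
   20,000 iterations is 1/20001 < 10⁻⁴). Exact backend: full enumeration,
   `p = count/total`, used automatically when the pooled sample admits at
   most 10,000 distinct splits. The study runner compares every temperature
   against 37 °C with session means as observations (n = 19 per group) and,
   labeled separately, with pooled epochs; the published-style tables use
   the session-means unit. No multiple-testing correction is applied across
   the five amplitude comparisons, matching the original analysis.
   A simulation harness (`calibration_study`) verifies the empirical type-I
   error rate (≈ 0.05 under a Gaussian null, n = 20 per group) and power.

## Synthetic-session generator

The generator is phenomenological — it aims to reproduce the statistical
signatures the pipeline measures, not cortical biophysics:

- **Oscillatory bands.** Four narrowband Gaussian processes (white noise
  band-passed around center frequencies 2.5, 6, 10, 18 Hz with bandwidths
  3, 4, 4, 10 Hz), unit RMS, mixed with gains 1.0/0.45/0.28/0.18
  (delta-dominated, as under anesthesia), over a 1/f (pink) background
  (gain 0.3). Each band carries a slow log-normal amplitude modulation
  (log-SD 0.02–0.42 per band, correlation time ≈ 0.6 s).
- **Suppression episodes.** Broadband multiplicative dips exp(−s(t)) shared
  by all bands and the background (Poisson onsets at 0.02 /s, Gaussian
  profiles of mean duration 4 s, mean depth 1.0 in log-amplitude),
  emulating the intermittent near-flattening of anesthesia EEG. These
  produce the deep lower tail of the epoch-power distribution that min–max
  normalization is sensitive to.
- **Sharp transients.** Sparse ~40 Hz wavelets (Poisson 0.08 /s, Gaussian
  envelope SD 20 ms, peak ≈ 4.9× background RMS, log-normal spread 0.2).
  Sitting above the analyzed 1–30 Hz bands, they set the session-wide
  signal extremes — and hence the amplitude normalization scale — while
  contributing almost nothing to band power.
- **Temperature coupling.** A global linear envelope E(T) = β₀ + β₁·T
  (shipped: β₁ = −0.068 per °C with E(37) = 1, so E(42) = 0.66) multiplies
  the whole signal; per-band fractional slopes (delta +0.062, theta −0.010,
  alpha −0.005, beta +0.068 per °C) shape how each band's power declines
  relative to the envelope. The positive delta/beta slopes partially offset
  the steep envelope for those bands; the transients follow the envelope
  alone.
- **Between-session variability.** Per-session log-normal jitter (SD 0.15)
  on each band gain, plus independent realizations of modulation,
  suppression and transients per session seed. Output is scaled to µV
  (≈ 70 µV RMS at 37 °C). Default sampling rate is 1 kHz (20 kHz is
  supported but pointless for 1–50 Hz content); all analysis code is
  rate-agnostic.

### Calibration

`calibrate_generator` tunes (envelope slope, noise gain, transient gain,
suppression depth, per-band modulation depths, per-band temperature slopes)
by coordinate descent against target summary statistics, evaluating each
candidate by running the full pipeline on a small study at a fixed
evaluation seed, and converging when amplitude targets are within 0.02 and
band-power targets within 0.05. The shipped defaults are the output of this
one-time procedure, targeting study-level mean normalized amplitudes of
0.461/0.341 at 37/42 °C and band-power means of 0.511/0.347 (delta),
0.509/0.259 (theta), 0.495/0.230 (alpha), 0.319/0.222 (beta). With the
shipped configuration, a 19-session study lands within ~0.03 of every
target except delta at 37 °C (≈ 0.44 vs 0.51, a known ceiling of the model:
the intrinsic Welch-estimator fluctuation of a 3-Hz-wide band bounds how
concentrated the delta epoch-power distribution can be).

## What the synthetic data does and does not show

Passing the recovery tests demonstrates that the pipeline's measurements,
summaries, and inference are internally consistent and recover the
statistical structure the generator encodes. It does not validate the
generator against real mouse EEG: real sessions have artifacts, non-
stationary anesthesia depth, day effects within animals (19 sessions from 4
mice are not independent), and across-session dispersion larger than the
generator produces (the shipped config yields across-session SDs of
~0.02–0.06 where a real study reports ~0.09–0.19; the study *means* are
calibrated, their dispersion is not). The model also contains no
biophysics: no neural-mass dynamics, no anesthetic pharmacokinetics, and no
brain-vs-rectal temperature distinction.

## Numerical choices and degenerate inputs

- Filter design (order, family) is a free choice; 4th-order Butterworth
  zero-phase is standard EEG practice and preserves peak timing.
- A constant signal cannot be min–max normalized and raises; a band with
  zero power range normalizes to all zeros with a logged warning.
- Permutation ties are counted as exceedances with a relative tolerance of
  1e−12, making the test conservative and the p-value invariant to adding a
  constant to all observations.
- EDF output quantizes to 16 bits over a symmetric range 5% beyond the
  signal extremes; an explicitly declared range that the signal exceeds is
  an error (no silent clipping). Summaries recomputed from disk agree with
  in-memory runs to < 1e−3.
- Session seeds are derived as study seed + session index; every
  Monte-Carlo test records its own derived seed, backend and iteration
  count. Identical manifest + seed reproduce byte-identical outputs.

## Problem sizes

The default study — 19 sessions × 25 min at 1 kHz (1.5 M samples/session,
300 epochs) — runs in well under a minute on one CPU, so tests and the
reproduction script use the full published study size; only incidental unit
tests use a compressed 5-min protocol at 500 Hz.
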