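"""Signal conditioning and epoching.

The analysis chain applied to every session: zero-phase 1–50 Hz bandpass,
session-wide min–max normalization to [0, 1], partition into contiguous 5-s
epochs, and per-epoch core-temperature assignment (mean over the epoch,
rounded half-up to the nearest integer °C; epochs outside 37–42 °C are
discarded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import SessionRecording

logger = logging.getLogger(__name__)

TEMP_RANGE_C = (37, 42)  # inclusive kept range of rounded temperatures


class FilterConfigError(ValueError):
    """Filter band incompatible with the sampling rate."""


class DegenerateSignalError(ValueError):
    """Constant signal cannot be min-max normalized."""


@dataclass(eq=False)
class EpochRecord:
    """A fixed-length slice of the (preprocessed) recording.

    ``kept`` is true exactly when ``rounded_temp`` falls inside the analyzed
    37–42 °C range.
    """

    session_id: str
    epoch_index: int
    start_time: float
    samples: np.ndarray
    mean_temp: float
    rounded_temp: int | None = None
    kept: bool = False


def bandpass_filter(
    signal: np.ndarray,
    sampling_rate: float,
    low: float = 1.0,
    high: float = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (applied forward and backward).

    The default 1–50 Hz band keeps the delta-to-beta range of anesthesia EEG
    while removing DC drift and high-frequency noise.
    """
    if sampling_rate <= 2.0 * high:
        raise FilterConfigError(
            f"sampling_rate {sampling_rate} Hz must exceed twice the upper "
            f"band edge ({high} Hz)"
        )
    if not 0 < low < high:
        raise FilterConfigError("band edges must satisfy 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def normalize_01(signal: np.ndarray) -> np.ndarray:
    """Affine map sending the signal's minimum to 0 and maximum to 1.

    Applied per session, after filtering; raises on a constant signal.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateSignalError("constant signal has no min-max range")
    return (x - lo) / (hi - lo)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up (41.5 -> 42)."""
    return int(np.floor(x + 0.5))


def assign_temperature(
    epoch: EpochRecord, temp_range: tuple[int, int] = TEMP_RANGE_C
) -> EpochRecord:
    """Set ``rounded_temp`` (half-up) and the keep/discard flag in place.

    The discard rule operates on the rounded value: a 36.6 °C epoch rounds to
    37 and is kept, a 36.4 °C epoch rounds to 36 and is discarded.
    """
    if not np.isfinite(epoch.mean_temp):
        raise ValueError("epoch mean temperature is not finite")
    epoch.rounded_temp = round_half_up(epoch.mean_temp)
    epoch.kept = temp_range[0] <= epoch.rounded_temp <= temp_range[1]
    return epoch


def make_epochs(
    rec: SessionRecording,
    epoch_length: float = 5.0,
    signal: np.ndarray | None = None,
    temp_range: tuple[int, int] = TEMP_RANGE_C,
) -> list[EpochRecord]:
    """Cut the recording into contiguous non-overlapping epochs from t = 0.

    ``signal`` (default: the raw EEG) lets the caller pass the filtered and
    normalized trace while the epoch temperatures still come from the
    recording's temperature channel, linearly interpolated onto the EEG time
    axis. A trailing partial epoch is dropped.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    x = rec.eeg if signal is None else np.asarray(signal, dtype=float)
    if x.size != rec.eeg.size:
        raise ValueError("signal override must match the recording length")
    samples_per_epoch = int(round(epoch_length * rec.sampling_rate))
    n_epochs = x.size // samples_per_epoch
    if n_epochs == 0:
        logger.warning(
            "recording %s shorter than one epoch (%.1f s); no epochs produced",
            rec.session_id, epoch_length,
        )
        return []
    temps = rec.temperature.interp(rec.times)
    epochs = []
    for k in range(n_epochs):
        sl = slice(k * samples_per_epoch, (k + 1) * samples_per_epoch)
        ep = EpochRecord(
            session_id=rec.session_id,
            epoch_index=k,
            start_time=k * epoch_length,
            samples=x[sl],
            mean_temp=float(np.mean(temps[sl])),
        )
        epochs.append(assign_temperature(ep, temp_range))
    return epochs


def preprocess_session(
    rec: SessionRecording,
    epoch_length: float = 5.0,
    low: float = 1.0,
    high: float = 50.0,
    temp_range: tuple[int, int] = TEMP_RANGE_C,
) -> list[EpochRecord]:
    """Full conditioning chain: bandpass, normalize to [0, 1], epoch, assign
    temperatures. Returns all epochs (kept and discarded)."""
    sig = normalize_01(bandpass_filter(rec.eeg, rec.sampling_rate, low, high))
    return make_epochs(rec, epoch_length, signal=sig, temp_range=temp_range)
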