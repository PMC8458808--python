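"""Band-power analysis.

Per kept 5-s epoch, a Welch power spectral density (2-s Hann segments, 50%
overlap, 0.5 Hz resolution) is integrated over the four canonical bands —
delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz (half-open intervals, so
shared edges are never double-counted) — then each band is min-max
normalized across the session's kept epochs and summarized per integer
temperature, within sessions and across the study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EpochRecord

logger = logging.getLogger(__name__)


class BandError(ValueError):
    """Empty or out-of-grid frequency band."""


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise BandError(f"band {self.name}: low must be < high")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
)

WELCH_SEGMENT_S = 2.0  # Hann segments, 50% overlap -> 0.5 Hz resolution


def epoch_power_spectrum(
    epoch: EpochRecord | np.ndarray, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of an epoch (2-s Hann segments, 50% overlap).

    Returns ``(freqs, psd)`` with 0.5 Hz frequency resolution.
    """
    x = epoch.samples if isinstance(epoch, EpochRecord) else np.asarray(epoch)
    nperseg = int(round(WELCH_SEGMENT_S * sampling_rate))
    if x.size < nperseg:
        raise ValueError(
            f"epoch of {x.size} samples shorter than one {WELCH_SEGMENT_S}-s "
            "Welch segment"
        )
    return sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False,
    )


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over the band.

    Band edges are half-open for assignment; numerically the trapezoid rule
    is applied on the closed grid interval [low, high], so that adjacent
    bands sharing an edge tile the total power exactly (each shared grid
    point contributes its half-trapezoids to each side once).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if band.low < freqs[0] or band.high > freqs[-1]:
        raise BandError(
            f"band {band.name} [{band.low}, {band.high}) outside the "
            f"frequency grid [{freqs[0]}, {freqs[-1]}]"
        )
    mask = (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)
    if mask.sum() < 2:
        raise BandError(f"band {band.name} covers fewer than two grid points")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def band_powers_by_epoch(
    epochs: list[EpochRecord],
    sampling_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Raw band powers for every epoch: DataFrame (rows = epoch order in the
    input, columns = band names)."""
    rows = []
    for e in epochs:
        freqs, psd = epoch_power_spectrum(e, sampling_rate)
        rows.append({b.name: band_power(freqs, psd, b) for b in bands})
    return pd.DataFrame(rows)


def normalize_band_powers(powers: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each band's power across the session's kept epochs.

    A band with zero range (all epochs equal) maps to all zeros with a
    logged warning.
    """
    if len(powers) < 2:
        raise ValueError("need at least 2 epochs to normalize band powers")
    out = {}
    for col in powers.columns:
        v = powers[col].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if hi <= lo:
            logger.warning("band %s has zero power range; normalized to 0", col)
            out[col] = np.zeros_like(v)
        else:
            out[col] = (v - lo) / (hi - lo)
    return pd.DataFrame(out, index=powers.index)


@dataclass
class BandPowerSummary:
    """Mean/SD/n of normalized band power per band and integer temperature.

    ``table`` has a (band, temperature) MultiIndex with columns mean/sd/n.
    """

    table: pd.DataFrame
    level: str = "session"
    session_id: str | None = None

    def mean_at(self, band: str, temp: int) -> float:
        return float(self.table.loc[(band, int(temp)), "mean"])

    def bands(self) -> list[str]:
        present = list(self.table.index.get_level_values(0).unique())
        canonical = [b.name for b in DEFAULT_BANDS if b.name in present]
        return canonical + [b for b in present if b not in canonical]


def summarize_bands_session(
    normalized: pd.DataFrame, epochs: list[EpochRecord]
) -> BandPowerSummary:
    """Mean normalized power per band per rounded temperature for one session.

    ``normalized`` rows must correspond one-to-one with ``epochs`` (kept
    epochs only).
    """
    if len(normalized) != len(epochs):
        raise ValueError("normalized powers and epochs must align")
    temps = np.array([int(e.rounded_temp) for e in epochs])
    rows = []
    for band in normalized.columns:
        v = normalized[band].to_numpy(dtype=float)
        for t in np.unique(temps):
            sel = v[temps == t]
            rows.append({
                "band": band, "temperature_c": int(t), "mean": sel.mean(),
                "sd": sel.std(ddof=1) if sel.size > 1 else np.nan,
                "n": sel.size,
            })
    table = pd.DataFrame(rows).set_index(["band", "temperature_c"])
    return BandPowerSummary(
        table=table, level="session", session_id=epochs[0].session_id
    )


def summarize_bands_study(
    session_summaries: list[BandPowerSummary],
) -> BandPowerSummary:
    """Mean/SD across session-level band means, per band and temperature."""
    if not session_summaries:
        raise ValueError("no session summaries")
    groups: dict[tuple[str, int], list[float]] = {}
    for s in session_summaries:
        for (band, t), row in s.table.iterrows():
            groups.setdefault((band, int(t)), []).append(float(row["mean"]))
    rows = []
    for (band, t), v in sorted(groups.items()):
        arr = np.asarray(v)
        rows.append({
            "band": band, "temperature_c": t, "mean": arr.mean(),
            "sd": arr.std(ddof=1) if arr.size > 1 else np.nan, "n": arr.size,
        })
    table = pd.DataFrame(rows).set_index(["band", "temperature_c"])
    return BandPowerSummary(table=table, level="study")
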