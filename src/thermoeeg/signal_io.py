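"""Session I/O: EDF for the EEG channel, CSV for core temperature, YAML/JSON
study manifests, and EEG/temperature alignment validation.

EDF (European Data Format) is the interchange format for the single
differential EEG channel. Writing uses a small built-in EDF encoder (16-bit,
one data record per second); reading goes through :mod:`mne`, whose
independent EDF parser doubles as a cross-check of the writer. The
temperature channel is a plain two-column CSV with the fixed header
``time_s,temp_c``.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SessionRecording, TemperatureProfile

logger = logging.getLogger(__name__)

TEMP_CSV_HEADER = "time_s,temp_c"
_DIG_MIN, _DIG_MAX = -32768, 32767


class AlignmentError(ValueError):
    """Temperature channel does not cover the EEG time span."""


class TemperatureParseError(ValueError):
    """Malformed temperature CSV (carries the offending line number)."""

    def __init__(self, path, line: int | None, message: str) -> None:
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = path
        self.line = line


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    eeg: np.ndarray,
    sampling_rate: float,
    path: str | Path,
    physical_range: tuple[float, float] | None = None,
    label: str | list[str] = "EEG",
    physical_dim: str = "uV",
) -> None:
    """Write an EDF file (16-bit, 1-s data records).

    ``eeg`` may be 1D (one channel) or 2D ``(n_channels, n_samples)``.
    ``physical_range`` defaults to a symmetric range 5% beyond each channel's
    extremes; an explicitly passed range that a signal exceeds raises (never
    silently clips). The signal length must be a whole number of seconds at
    ``sampling_rate``.
    """
    x = np.atleast_2d(np.asarray(eeg, dtype=float))
    n_chan, n = x.shape
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n % fs != 0:
        raise ValueError(
            f"signal length {n} is not a whole number of seconds at "
            f"{fs} Hz; trim or pad before writing"
        )
    n_records = n // fs
    labels = [label] * n_chan if isinstance(label, str) else list(label)
    if len(labels) != n_chan:
        raise ValueError("need one label per channel")

    ranges = []
    for c in range(n_chan):
        if physical_range is None:
            amax = float(np.max(np.abs(x[c]))) if n else 1.0
            bound = max(amax * 1.05, 1e-6)
            ranges.append((-bound, bound))
        else:
            phys_min, phys_max = map(float, physical_range)
            if phys_min >= phys_max:
                raise ValueError("physical_range must be increasing")
            if np.min(x[c]) < phys_min or np.max(x[c]) > phys_max:
                raise ValueError(
                    "signal exceeds the declared physical range "
                    f"[{phys_min}, {phys_max}]; refusing to clip"
                )
            ranges.append((phys_min, phys_max))

    digital = np.empty_like(x, dtype="<i2")
    for c, (lo, hi) in enumerate(ranges):
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        digital[c] = np.round((x[c] - lo) * scale + _DIG_MIN).astype("<i2")

    def fmt(v: float) -> str:
        return f"{v:.8g}"[:8]

    def sig_fields(width: int, values) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2021 X X X", 80),
        _edf_field("01.01.21", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * n_chan, 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field("1", 8),                # record duration, seconds
        _edf_field(n_chan, 4),
        sig_fields(16, labels),
        sig_fields(80, [""] * n_chan),     # transducer
        sig_fields(8, [physical_dim] * n_chan),
        sig_fields(8, [fmt(r[0]) for r in ranges]),
        sig_fields(8, [fmt(r[1]) for r in ranges]),
        sig_fields(8, [_DIG_MIN] * n_chan),
        sig_fields(8, [_DIG_MAX] * n_chan),
        sig_fields(80, ["BP 1-50Hz"] * n_chan),  # prefiltering note
        sig_fields(8, [fs] * n_chan),      # samples per record
        sig_fields(32, [""] * n_chan),
    ])
    # records interleave channels: ch0 second, ch1 second, ...
    data = digital.reshape(n_chan, n_records, fs).transpose(1, 0, 2)
    path = Path(path)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(np.ascontiguousarray(data).tobytes())
    except OSError as exc:
        raise OSError(f"cannot write EDF file {path}: {exc}") from exc


def write_temperature_csv(profile: TemperatureProfile, path: str | Path) -> None:
    """Write the temperature channel as ``time_s,temp_c`` rows."""
    path = Path(path)
    try:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(TEMP_CSV_HEADER + "\n")
            for t, c in zip(profile.times, profile.temps):
                fh.write(f"{t:.3f},{c:.4f}\n")
    except OSError as exc:
        raise OSError(f"cannot write temperature CSV {path}: {exc}") from exc


def write_session(
    rec: SessionRecording,
    eeg_path: str | Path,
    temp_path: str | Path,
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write one session: EDF (EEG, µV) plus its temperature CSV sidecar."""
    write_edf(rec.eeg, rec.sampling_rate, eeg_path,
              physical_range=physical_range, label="EEG")
    write_temperature_csv(rec.temperature, temp_path)


def read_temperature_csv(path: str | Path) -> TemperatureProfile:
    """Parse a ``time_s,temp_c`` CSV into a temperature profile.

    Raises :class:`TemperatureParseError` with the 1-based line number of the
    first malformed row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"temperature file not found: {path}")
    with open(path, encoding="ascii", errors="replace") as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != TEMP_CSV_HEADER:
            raise TemperatureParseError(
                path, 1, f"expected header {TEMP_CSV_HEADER!r}, got {header!r}"
            )
        times, temps = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TemperatureParseError(
                    path, lineno, f"expected 2 comma-separated fields, got {len(parts)}"
                )
            try:
                t, c = float(parts[0]), float(parts[1])
            except ValueError:
                raise TemperatureParseError(
                    path, lineno, f"non-numeric value in {line!r}"
                ) from None
            if not (np.isfinite(t) and np.isfinite(c)):
                raise TemperatureParseError(path, lineno, "non-finite value")
            times.append(t)
            temps.append(c)
    if len(times) < 2:
        raise TemperatureParseError(path, None, "fewer than 2 temperature samples")
    times_a = np.asarray(times)
    if np.any(np.diff(times_a) <= 0):
        bad = int(np.flatnonzero(np.diff(times_a) <= 0)[0]) + 3
        raise TemperatureParseError(path, bad, "time_s not strictly increasing")
    return TemperatureProfile(
        times=times_a, temps=np.asarray(temps),
        phase=np.full(times_a.size, "unknown"),
    )


def read_session(
    eeg_path: str | Path,
    temp_path: str | Path,
    session_id: str | None = None,
    epoch_length: float = 5.0,
    return_report: bool = False,
):
    """Load an EDF + temperature CSV pair into an aligned session.

    The first EDF channel is taken as the active-electrode EEG (a warning is
    logged if more channels are present). The temperature series must cover
    the EEG time span to within one epoch length; constant extrapolation is
    applied at the edges for any smaller shortfall. Optionally returns a
    validation report (duration mismatch, sampling gaps).
    """
    import mne

    eeg_path = Path(eeg_path)
    if not eeg_path.exists():
        raise FileNotFoundError(f"EDF file not found: {eeg_path}")
    raw = mne.io.read_raw_edf(str(eeg_path), preload=True, verbose="error")
    if len(raw.ch_names) > 1:
        logger.warning(
            "%s has %d channels; using the first (%s) as the EEG channel",
            eeg_path.name, len(raw.ch_names), raw.ch_names[0],
        )
    eeg = raw.get_data(picks=[0])[0] * 1e6  # mne returns volts; store µV
    fs = float(raw.info["sfreq"])

    profile = read_temperature_csv(temp_path)
    eeg_span = eeg.size / fs
    temp_span = float(profile.times[-1] - profile.times[0])
    shortfall = eeg_span - (temp_span + profile.times[0])
    if shortfall > epoch_length:
        raise AlignmentError(
            f"temperature channel ({temp_span:.1f} s) falls short of the EEG "
            f"span ({eeg_span:.1f} s) by more than one epoch ({epoch_length} s)"
        )

    dt = np.diff(profile.times)
    gaps = np.flatnonzero(dt > 2.0 * np.median(dt))
    report = {
        "eeg_span_s": eeg_span,
        "temperature_span_s": temp_span,
        "duration_mismatch_s": float(shortfall),
        "n_gaps": int(gaps.size),
        "gap_times_s": profile.times[gaps].tolist(),
    }
    if report["n_gaps"]:
        logger.warning("%s: %d gaps in the temperature channel",
                       Path(temp_path).name, report["n_gaps"])

    rec = SessionRecording(
        eeg=eeg, sampling_rate=fs, temperature=profile,
        session_id=session_id or eeg_path.stem, seed=None,
    )
    return (rec, report) if return_report else rec


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------


@dataclass
class SessionEntry:
    session_id: str
    seed: int
    eeg_path: str | None = None
    temperature_path: str | None = None


@dataclass
class StudyManifest:
    """Declarative description of a study: sessions plus analysis parameters.

    Sessions with file paths are read from disk; sessions without paths are
    simulated with the calibrated generator at their recorded seed.
    """

    sessions: list[SessionEntry] = field(default_factory=list)
    epoch_length: float = 5.0
    filter_low: float = 1.0
    filter_high: float = 50.0
    temp_range: tuple[int, int] = (37, 42)
    n_iterations: int = 20_000
    generator: dict | None = None  # overrides of calibrated generator fields

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValueError("session_ids must be unique")
        self.temp_range = (int(self.temp_range[0]), int(self.temp_range[1]))

    @classmethod
    def simulated(cls, n_sessions: int = 19, seed: int = 1, **params) -> "StudyManifest":
        """Manifest for an all-synthetic study; session seeds are seed + index."""
        sessions = [
            SessionEntry(session_id=f"session_{i:02d}", seed=int(seed) + i)
            for i in range(n_sessions)
        ]
        return cls(sessions=sessions, **params)

    def to_dict(self) -> dict:
        return {
            "sessions": [
                {k: v for k, v in vars(s).items() if v is not None}
                for s in self.sessions
            ],
            "epoch_length": self.epoch_length,
            "filter_low": self.filter_low,
            "filter_high": self.filter_high,
            "temp_range": list(self.temp_range),
            "n_iterations": self.n_iterations,
            **({"generator": self.generator} if self.generator else {}),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "StudyManifest":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        sessions = [SessionEntry(**s) for s in raw.pop("sessions", [])]
        raw["temp_range"] = tuple(raw.get("temp_range", (37, 42)))
        return cls(sessions=sessions, **raw)

    def validate_files(self) -> None:
        """Check that every referenced session file exists."""
        missing = []
        for s in self.sessions:
            for p in (s.eeg_path, s.temperature_path):
                if p is not None and not Path(p).exists():
                    missing.append(p)
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")
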