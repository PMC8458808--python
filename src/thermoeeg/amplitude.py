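"""Peak-to-peak amplitude analysis.

Per kept epoch, the statistic is the maximum peak-to-peak amplitude (max
minus min of the normalized samples). Summaries are computed per integer
temperature, first across a session's epochs, then across sessions (each
session weighted equally), and the temperature dependence is characterized
by an ordinary least-squares fit of the per-temperature means on temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .preprocess import EpochRecord


@dataclass
class TemperatureSummary:
    """Mean/SD/n of an amplitude statistic per integer temperature.

    ``sd`` is the sample standard deviation (n-1 denominator) and is NaN
    (undefined) where n < 2. ``level`` records whether rows summarize epochs
    within a session or session means across the study.
    """

    temps: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    level: str = "session"
    session_id: str | None = None
    values: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=int)
        order = np.argsort(self.temps)
        self.temps = self.temps[order]
        self.mean = np.asarray(self.mean, dtype=float)[order]
        self.sd = np.asarray(self.sd, dtype=float)[order]
        self.n = np.asarray(self.n, dtype=int)[order]

    def mean_at(self, temp: int) -> float:
        idx = np.flatnonzero(self.temps == temp)
        if idx.size == 0:
            raise KeyError(f"no data at {temp} °C")
        return float(self.mean[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature_c": self.temps, "mean": self.mean, "sd": self.sd,
             "n": self.n}
        )


@dataclass
class LinearFit:
    """OLS fit y = slope*x + intercept of amplitude on temperature (°C)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, temp: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(temp, dtype=float)


def max_peak_to_peak(epoch: EpochRecord | np.ndarray) -> float:
    """Maximum peak-to-peak amplitude of an epoch: max(samples) - min(samples)."""
    x = epoch.samples if isinstance(epoch, EpochRecord) else np.asarray(epoch)
    if x.size == 0:
        raise ValueError("empty epoch has no peak-to-peak amplitude")
    return float(np.max(x) - np.min(x))


def _group_stats(groups: dict[int, np.ndarray], level: str,
                 session_id: str | None = None) -> TemperatureSummary:
    temps = sorted(groups)
    means, sds, ns = [], [], []
    for t in temps:
        v = np.asarray(groups[t], dtype=float)
        means.append(v.mean())
        sds.append(v.std(ddof=1) if v.size > 1 else np.nan)
        ns.append(v.size)
    return TemperatureSummary(
        temps=np.array(temps), mean=np.array(means), sd=np.array(sds),
        n=np.array(ns), level=level, session_id=session_id,
        values={t: np.asarray(groups[t], dtype=float) for t in temps},
    )


def summarize_session(
    epochs: list[EpochRecord],
    amplitudes: dict[EpochRecord, float] | None = None,
) -> TemperatureSummary:
    """Mean/SD/n of the max peak-to-peak amplitude across a session's kept
    epochs, per rounded temperature."""
    kept = [e for e in epochs if e.kept]
    if not kept:
        raise ValueError("no kept epochs to summarize")
    groups: dict[int, list[float]] = {}
    for e in kept:
        a = amplitudes[e] if amplitudes is not None else max_peak_to_peak(e)
        groups.setdefault(int(e.rounded_temp), []).append(a)
    return _group_stats(
        {t: np.array(v) for t, v in groups.items()},
        level="session", session_id=kept[0].session_id,
    )


def summarize_study(session_summaries: list[TemperatureSummary]) -> TemperatureSummary:
    """Mean/SD across the session-level means, per temperature (each session
    weighted equally). Temperatures present in no session are omitted."""
    if not session_summaries:
        raise ValueError("no session summaries")
    groups: dict[int, list[float]] = {}
    for s in session_summaries:
        for t, m in zip(s.temps, s.mean):
            groups.setdefault(int(t), []).append(float(m))
    return _group_stats({t: np.array(v) for t, v in groups.items()}, level="study")


def percent_reduction(
    summary: TemperatureSummary | list[TemperatureSummary],
    ref_temp: int = 37,
    mode: str = "study",
) -> dict[int, float] | dict[int, tuple[float, float]]:
    """Percent amplitude reduction relative to ``ref_temp``.

    mode="study": ``100*(mean_ref - mean_T)/mean_ref`` on the study-level
    means (pass a study :class:`TemperatureSummary`). mode="per_session":
    compute the reduction within each session, then report mean ± SD across
    sessions (pass the list of session summaries). The two orders of
    averaging differ in general; both are exposed.
    """
    if mode == "study":
        if not isinstance(summary, TemperatureSummary):
            raise TypeError("study mode expects a single TemperatureSummary")
        ref = summary.mean_at(ref_temp)
        if ref == 0:
            raise ZeroDivisionError("reference mean amplitude is zero")
        return {
            int(t): 100.0 * (ref - m) / ref for t, m in zip(summary.temps, summary.mean)
        }
    if mode == "per_session":
        if isinstance(summary, TemperatureSummary):
            raise TypeError("per_session mode expects a list of session summaries")
        per_temp: dict[int, list[float]] = {}
        for s in summary:
            if ref_temp not in s.temps:
                continue
            ref = s.mean_at(ref_temp)
            if ref == 0:
                raise ZeroDivisionError("reference mean amplitude is zero")
            for t, m in zip(s.temps, s.mean):
                per_temp.setdefault(int(t), []).append(100.0 * (ref - m) / ref)
        return {
            t: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
            for t, v in sorted(per_temp.items())
        }
    raise ValueError("mode must be 'study' or 'per_session'")


def fit_linear(summary: TemperatureSummary) -> LinearFit:
    """Unweighted OLS of the per-temperature mean amplitudes on temperature."""
    if summary.temps.size < 3:
        raise ValueError("need at least 3 temperature levels for a linear fit")
    res = spstats.linregress(summary.temps.astype(float), summary.mean)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(summary.temps.size),
    )
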