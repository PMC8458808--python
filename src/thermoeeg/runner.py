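"""Study orchestration: simulate/load -> preprocess -> analyze -> test -> report.

One seeded entry point runs the whole study: every session is simulated (or
read from disk), conditioned, epoched, and summarized; amplitude and
band-power summaries are aggregated across sessions; each temperature is
compared against the 37 °C baseline with permutation tests (both with
session means and with pooled epochs as observations, labeled as such); and
the Table-1/Table-2-style CSV outputs are written with full provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplitude import (
    LinearFit,
    TemperatureSummary,
    fit_linear,
    max_peak_to_peak,
    percent_reduction,
    summarize_session,
    summarize_study,
)
from .preprocess import bandpass_filter, make_epochs, normalize_01
from .signal_io import StudyManifest, read_session
from .spectral import (
    BandPowerSummary,
    DEFAULT_BANDS,
    band_powers_by_epoch,
    normalize_band_powers,
    summarize_bands_session,
    summarize_bands_study,
)
from .stats import permutation_test
from .synthetic import CALIBRATED_GENERATOR, make_temperature_profile, synthesize_eeg

logger = logging.getLogger(__name__)

_STATS_SEED_OFFSET = 100_000  # keeps per-test seeds clear of session seeds


@dataclass
class StudyResult:
    """Everything a study run produces, plus provenance."""

    amplitude_summary: TemperatureSummary
    band_summary: BandPowerSummary
    session_amplitude_summaries: list[TemperatureSummary]
    session_band_summaries: list[BandPowerSummary]
    fits: dict[str, LinearFit]
    tests: pd.DataFrame
    reductions_study: dict[int, float]
    reductions_per_session: dict[int, tuple[float, float]]
    provenance: dict = field(default_factory=dict)

    def table1(self) -> pd.DataFrame:
        """Amplitude per temperature with session-mean permutation p-values."""
        df = self.amplitude_summary.to_frame()
        pmap = {
            int(r["group"]): r["p_value"]
            for _, r in self.tests.iterrows()
            if r["quantity"] == "amplitude" and r["unit"] == "session_means"
        }
        df["p_vs_37"] = [pmap.get(int(t), np.nan) for t in df["temperature_c"]]
        return df

    def table2(self) -> pd.DataFrame:
        """Band power at 37 vs 42 °C with permutation p-values."""
        t = self.band_summary.table
        pmap = {
            r["group"]: r["p_value"]
            for _, r in self.tests.iterrows()
            if r["quantity"] != "amplitude" and r["unit"] == "session_means"
        }
        rows = []
        for band in self.band_summary.bands():
            rows.append({
                "band": band,
                "mean_37": t.loc[(band, 37), "mean"],
                "sd_37": t.loc[(band, 37), "sd"],
                "mean_42": t.loc[(band, 42), "mean"],
                "sd_42": t.loc[(band, 42), "sd"],
                "p": pmap.get(band, np.nan),
            })
        return pd.DataFrame(rows)


def _session_recording(entry, manifest: StudyManifest, seed: int, index: int):
    if entry.eeg_path is not None:
        return read_session(entry.eeg_path, entry.temperature_path,
                            session_id=entry.session_id,
                            epoch_length=manifest.epoch_length)
    gen = CALIBRATED_GENERATOR
    if manifest.generator:
        gen = gen.replace(**manifest.generator)
    profile = make_temperature_profile()
    return synthesize_eeg(profile, gen.replace(seed=seed + index),
                          session_id=entry.session_id)


def analyze_session(rec, manifest: StudyManifest):
    """Preprocess one recording and compute its amplitude and band summaries."""
    sig = normalize_01(
        bandpass_filter(rec.eeg, rec.sampling_rate,
                        manifest.filter_low, manifest.filter_high)
    )
    epochs = [
        e for e in make_epochs(rec, manifest.epoch_length, signal=sig,
                               temp_range=manifest.temp_range)
        if e.kept
    ]
    if not epochs:
        raise ValueError(f"session {rec.session_id}: no kept epochs")
    amps = {e: max_peak_to_peak(e) for e in epochs}
    amp_summary = summarize_session(epochs, amps)
    raw_powers = band_powers_by_epoch(epochs, rec.sampling_rate, DEFAULT_BANDS)
    band_summary = summarize_bands_session(normalize_band_powers(raw_powers), epochs)
    return amp_summary, band_summary


def _config_hash(manifest: StudyManifest, seed: int) -> str:
    gen = CALIBRATED_GENERATOR
    if manifest.generator:
        gen = gen.replace(**manifest.generator)
    blob = json.dumps(
        {"manifest": manifest.to_dict(), "seed": seed,
         "generator": {k: v for k, v in vars(gen).items()}},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(
    manifest: StudyManifest, seed: int = 1, outdir: str | Path | None = None
) -> StudyResult:
    """Run the full study deterministically from ``manifest`` + ``seed``.

    Simulated sessions use derived seeds ``seed + index``; every permutation
    test records its own derived seed. With ``outdir`` set, writes
    ``table1.csv``, ``table2.csv``, ``fits.csv``, ``tests.csv``, and
    ``report.txt``.
    """
    if not manifest.sessions:
        raise ValueError("manifest lists no sessions")
    manifest.validate_files()

    amp_summaries: list[TemperatureSummary] = []
    band_summaries: list[BandPowerSummary] = []
    fits: dict[str, LinearFit] = {}
    failures: list[str] = []
    for i, entry in enumerate(manifest.sessions):
        try:
            rec = _session_recording(entry, manifest, seed, i)
            a, b = analyze_session(rec, manifest)
        except Exception as exc:  # collect, then abort listing all failures
            failures.append(f"{entry.session_id}: {exc}")
            continue
        amp_summaries.append(a)
        band_summaries.append(b)
        if a.temps.size >= 3:
            fits[entry.session_id] = fit_linear(a)
        logger.info("analyzed %s (%d temperatures)", entry.session_id, a.temps.size)
    if failures:
        raise RuntimeError(
            "study aborted; failing sessions:\n  " + "\n  ".join(failures)
        )

    study_amp = summarize_study(amp_summaries)
    study_bands = summarize_bands_study(band_summaries)
    if study_amp.temps.size >= 3:
        fits["study"] = fit_linear(study_amp)

    tests = _run_comparisons(amp_summaries, band_summaries, manifest, seed)

    red_study = percent_reduction(study_amp, mode="study") \
        if 37 in study_amp.temps else {}
    red_per_session = percent_reduction(amp_summaries, mode="per_session") \
        if 37 in study_amp.temps else {}

    result = StudyResult(
        amplitude_summary=study_amp,
        band_summary=study_bands,
        session_amplitude_summaries=amp_summaries,
        session_band_summaries=band_summaries,
        fits=fits,
        tests=tests,
        reductions_study=red_study,
        reductions_per_session=red_per_session,
        provenance={
            "study_seed": seed,
            "session_seeds": {
                e.session_id: (seed + i if e.eeg_path is None else e.seed)
                for i, e in enumerate(manifest.sessions)
            },
            "n_sessions": len(manifest.sessions),
            "config_hash": _config_hash(manifest, seed),
            "software_version": __version__,
            "welch": "2-s Hann segments, 50% overlap",
        },
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _run_comparisons(amp_summaries, band_summaries, manifest, seed) -> pd.DataFrame:
    """Permutation tests of every temperature against 37 °C.

    Amplitude: 38..42 vs 37, with session means and with pooled epochs as
    observations (both reported, labeled by ``unit``). Band power: 42 vs 37
    per band, same two units.
    """
    rows = []
    k = 0

    def compare(quantity, group_label, unit, a, b):
        nonlocal k
        if len(a) == 0 or len(b) == 0 or len(a) + len(b) < 3:
            return
        res = permutation_test(a, b, n_iterations=manifest.n_iterations,
                               seed=seed + _STATS_SEED_OFFSET + k)
        k += 1
        rows.append({
            "quantity": quantity, "group": group_label, "reference": 37,
            "unit": unit, "n_a": len(a), "n_b": len(b),
            "observed_stat": res.observed_stat, "p_value": res.p_value,
            "backend": res.backend, "n_iterations": res.n_iterations,
            "seed": res.seed,
        })

    def session_means(summaries, temp):
        return [s.mean_at(temp) for s in summaries if temp in s.temps]

    def pooled(summaries, temp):
        vals = [s.values[temp] for s in summaries if temp in s.values]
        return np.concatenate(vals) if vals else np.array([])

    temps = sorted({int(t) for s in amp_summaries for t in s.temps})
    for t in temps:
        if t == 37:
            continue
        compare("amplitude", t, "session_means",
                session_means(amp_summaries, 37), session_means(amp_summaries, t))
        compare("amplitude", t, "pooled_epochs",
                pooled(amp_summaries, 37), pooled(amp_summaries, t))

    for band in band_summaries[0].bands() if band_summaries else []:
        def band_means(temp):
            out = []
            for s in band_summaries:
                try:
                    out.append(s.mean_at(band, temp))
                except KeyError:
                    pass
            return out
        compare(band, band, "session_means", band_means(37), band_means(42))
    return pd.DataFrame(rows)


def write_outputs(result: StudyResult, outdir: str | Path) -> None:
    """Write the CSV outputs and the text report (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table1().to_csv(outdir / "table1.csv", index=False)
    result.table2().to_csv(outdir / "table2.csv", index=False)
    fits = pd.DataFrame(
        [{"session_id": sid, "slope": f.slope, "intercept": f.intercept,
          "r_squared": f.r_squared, "n_points": f.n_points}
         for sid, f in result.fits.items()]
    )
    fits.to_csv(outdir / "fits.csv", index=False)
    result.tests.to_csv(outdir / "tests.csv", index=False)
    (outdir / "report.txt").write_text(make_report(result))


def make_report(result: StudyResult) -> str:
    """Render a human-readable study report."""
    lines = []
    prov = result.provenance
    lines.append("Hyperthermia EEG study report")
    lines.append("=" * 29)
    lines.append(f"software version: {prov.get('software_version', '?')}")
    lines.append(f"config hash: {prov.get('config_hash', '?')}")
    lines.append(f"study seed: {prov.get('study_seed', '?')}; "
                 f"sessions: {prov.get('n_sessions', '?')}")
    lines.append("")
    lines.append("Amplitude vs temperature (across sessions)")
    lines.append("Temperature (°C)  Mean    SD      n   p (vs. 37°C)")
    t1 = result.table1()
    for _, r in t1.iterrows():
        p = "–" if int(r["temperature_c"]) == 37 or np.isnan(r["p_vs_37"]) \
            else f"{r['p_vs_37']:.4g}"
        sd = "–" if np.isnan(r["sd"]) else f"{r['sd']:.3f}"
        lines.append(
            f"{int(r['temperature_c']):>4d}             "
            f"{r['mean']:.3f}   {sd:>6}  {int(r['n']):>2d}  {p}"
        )
    if "study" in result.fits:
        f = result.fits["study"]
        lines.append("")
        lines.append(
            f"study regression: y = {f.slope:.4f}x + {f.intercept:.3f}; "
            f"R² = {f.r_squared:.3f}"
        )
    if result.reductions_study:
        lines.append("")
        lines.append("percent reduction vs 37°C (study means / per-session mean±SD):")
        for t in sorted(result.reductions_study):
            if t == 37:
                continue
            s = result.reductions_study[t]
            ps = result.reductions_per_session.get(t)
            ps_txt = f"{ps[0]:.2f}% (±{ps[1]:.2f})" if ps else "–"
            lines.append(f"  37→{t}°C: {s:.2f}% / {ps_txt}")
    lines.append("")
    lines.append("Normalized band power, 37°C vs 42°C (across sessions)")
    lines.append("Band    Mean37  SD37   Mean42  SD42   p")
    for _, r in result.table2().iterrows():
        lines.append(
            f"{r['band']:<7} {r['mean_37']:.3f}  {r['sd_37']:.3f}  "
            f"{r['mean_42']:.3f}  {r['sd_42']:.3f}  {r['p']:.4g}"
        )
    lines.append("")
    lines.append(f"session seeds: {prov.get('session_seeds', {})}")
    return "\n".join(lines) + "\n"
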