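"""End-to-end orchestration: simulate/load → periodogram → waveform → phase
mapping → immune fold-change statistics, with seeded determinism and a
manifest recording the configuration hash.

All stages run in memory first; files are written only after every stage has
succeeded, so a failed run never leaves partial outputs behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate, spectral, stats, waveform
from .series import TimeSeries, cohort_to_tidy, series_from_tidy, validate_tidy

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class WindowConfig:
    """A named source-species cycle stage in days (e.g. macaque luteal 16-25
    of a 32-day cycle)."""

    name: str
    day_start: float
    day_end: float
    cycle_length: float


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    preset: str | None = "mouse-pseudopregnancy"
    input_csv: str | None = None
    analyte: str = "progesterone"
    oversample: float = 5.0
    max_period_fraction: float = 1.0
    fap_method: str = "bootstrap"
    n_resamples: int = 999
    windows: list[WindowConfig] = field(default_factory=list)
    source_peak_day: float | None = None
    reference_phase: str | None = None
    immune: bool = False
    immune_population: str = "NK"
    immune_baseline_count: float = 200.0
    immune_fold_amplitude: float = 4.0
    immune_dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.windows = [
            w if isinstance(w, WindowConfig) else WindowConfig(**w)
            for w in self.windows
        ]
        if self.preset is None and self.input_csv is None:
            raise ValueError("config needs a preset or an input_csv")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_macaque_windows() -> list[WindowConfig]:
    """The luteal and late-luteal stages of the 32-day macaque cycle."""
    return [
        WindowConfig("luteal", 16.0, 25.0, 32.0),
        WindowConfig("late_luteal", 25.0, 33.0, 32.0),
    ]


@dataclass
class AnimalResult:
    series: TimeSeries
    periodogram: spectral.Periodogram
    peak: spectral.PeriodogramPeak
    fap: spectral.FAPResult
    fit: waveform.SinusoidFit
    mapped_windows: list[waveform.DayWindow] = field(default_factory=list)


@dataclass
class PipelineResult:
    config: PipelineConfig
    animals: list[AnimalResult]
    cohort_mean_period: float
    cohort_period_range: tuple[float, float]
    hormone_table: pd.DataFrame
    fold_table: pd.DataFrame | None = None
    test_table: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - relabel with stage
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage=%s elapsed=%.3fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def _obtain_cohort(config: PipelineConfig) -> tuple[list[TimeSeries], simulate.HormoneCycleSpec | None]:
    if config.input_csv is not None:
        df = validate_tidy(pd.read_csv(config.input_csv))
        ids = sorted(df.loc[df["analyte"] == config.analyte, "animal_id"].astype(str).unique())
        if not ids:
            raise ValueError(f"no {config.analyte!r} series in {config.input_csv}")
        return [series_from_tidy(df, a, config.analyte) for a in ids], None
    spec = simulate.PRESETS[config.preset](seed=config.seed)
    return simulate.generate_cohort(spec), spec


@_stage("spectral")
def _analyze_animal(config: PipelineConfig, index: int, ts: TimeSeries) -> AnimalResult:
    norm = spectral.normalize_series(ts)
    grid = spectral.build_frequency_grid(
        norm, oversample=config.oversample,
        max_period_fraction=config.max_period_fraction,
    )
    pg = spectral.compute_periodogram(norm, grid)
    peak = spectral.find_dominant_peak(pg)
    fap = spectral.false_alarm_probability(
        norm, peak, grid, method=config.fap_method,
        n_resamples=config.n_resamples, seed=config.seed * 1000 + index,
    )
    fit = waveform.fit_waveform(norm, peak)
    return AnimalResult(series=norm, periodogram=pg, peak=peak, fap=fap, fit=fit)


def _source_fit(config: PipelineConfig) -> waveform.SinusoidFit | None:
    """Nominal source-species fit used to express configured day windows as
    angles: unit sinusoid with the window's cycle length, peaking at
    source_peak_day."""
    if not config.windows:
        return None
    cycle = config.windows[0].cycle_length
    peak_day = config.source_peak_day
    if peak_day is None:
        peak_day = 0.25 * cycle  # peak angle pi/2 at quarter cycle by default
    f = 1.0 / cycle
    phi = 0.5 * math.pi - 2.0 * math.pi * f * peak_day
    return waveform.SinusoidFit(
        frequency=f, A=math.cos(phi), B=math.sin(phi), C=1.0,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return the in-memory result bundle."""
    cohort, spec = _obtain_cohort(config)
    animals = [_analyze_animal(config, i, ts) for i, ts in enumerate(cohort)]

    periods = [a.peak.period for a in animals]
    mean_period = float(np.mean(periods))
    period_range = (float(min(periods)), float(max(periods)))

    src_fit = _source_fit(config)
    phase_windows: list[waveform.PhaseWindow] = []
    if src_fit is not None:
        dws = [
            waveform.DayWindow(w.name, w.day_start, w.day_end, w.cycle_length)
            for w in config.windows
        ]
        phase_windows = [waveform.day_window_to_phase(src_fit, dw) for dw in dws]
        for a in animals:
            a.mapped_windows = [
                waveform.phase_to_day_window(a.fit, pw) for pw in phase_windows
            ]

    hormone_table = cohort_to_tidy([a.series for a in animals])

    fold_table = None
    test_table = None
    if config.immune and spec is not None:
        fold_table, test_table = _immune_stage(config, spec, animals, phase_windows)

    return PipelineResult(
        config=config,
        animals=animals,
        cohort_mean_period=mean_period,
        cohort_period_range=period_range,
        hormone_table=hormone_table,
        fold_table=fold_table,
        test_table=test_table,
    )


@_stage("immune")
def _immune_stage(config, spec, animals, phase_windows):
    ispec = simulate.ImmuneCountSpec(
        population=config.immune_population,
        baseline_count=config.immune_baseline_count,
        fold_amplitude=config.immune_fold_amplitude,
        peak_angle=0.5 * math.pi,
        dispersion=config.immune_dispersion,
        hormone=spec,
        seed=config.seed + 1,
    )
    counts = simulate.generate_immune_counts(ispec, spec.sampling_days)
    windows = phase_windows or [
        waveform.PhaseWindow("peak_half", 0.0, math.pi),
    ]
    counts["phase"] = waveform.assign_phase_labels(
        counts["phase_angle"].to_numpy(), windows
    )
    counts = counts.rename(columns={"count": "value"})
    fold_table = stats.fold_change_vs_reference(
        counts, reference=config.reference_phase, day_col="day"
    )
    test_table = stats.test_folds_by_group(fold_table)
    return fold_table, test_table


def write_bundle(result: PipelineResult, outdir) -> dict:
    """Serialize a result bundle to CSV/JSON files plus a manifest.

    Rerunning the same configuration reproduces the files byte-for-byte
    (no timestamps are written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, object] = {}

    result.hormone_table.to_csv(outdir / "hormone_series.csv", index=False)
    files["hormone_series.csv"] = "tidy hormone series (mean-normalized)"

    pg_frames = []
    for a in result.animals:
        pg_frames.append(
            pd.DataFrame(
                {
                    "animal_id": a.series.animal_id,
                    "frequency": a.periodogram.grid.frequencies,
                    "period": 1.0 / a.periodogram.grid.frequencies,
                    "power": a.periodogram.power,
                }
            )
        )
    pd.concat(pg_frames, ignore_index=True).to_csv(
        outdir / "periodograms.csv", index=False
    )
    files["periodograms.csv"] = "per-animal least-squares periodograms"

    summary = {
        "cohort_mean_period_days": result.cohort_mean_period,
        "cohort_period_range_days": list(result.cohort_period_range),
        "animals": [
            {
                "animal_id": a.series.animal_id,
                "peak": {
                    "frequency": a.peak.frequency,
                    "period": a.peak.period,
                    "power": a.peak.power,
                    "degenerate": a.peak.degenerate,
                },
                "fap": {
                    "fap": a.fap.fap,
                    "method": a.fap.method,
                    "n_resamples": a.fap.n_resamples,
                    "seed": a.fap.seed,
                },
                "fit": a.fit.to_dict(),
                "mapped_windows": [
                    {
                        "name": w.name,
                        "segments_days": w.split(),
                        "cycle_length": w.cycle_length,
                    }
                    for w in a.mapped_windows
                ],
            }
            for a in result.animals
        ],
    }
    _dump_json(summary, outdir / "summary.json")
    files["summary.json"] = "peaks, FAPs, fits, mapped windows, cohort summary"

    if result.fold_table is not None:
        result.fold_table.to_csv(outdir / "fold_changes.csv", index=False)
        files["fold_changes.csv"] = "per-animal immune fold changes"
    if result.test_table is not None:
        result.test_table.to_csv(outdir / "fold_tests.csv", index=False)
        files["fold_tests.csv"] = "signed-rank tests with FDR adjustment"

    manifest = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash,
        "seed": result.config.seed,
        "files": files,
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
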