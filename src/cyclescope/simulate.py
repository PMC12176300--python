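"""Seeded synthetic hormone and immune time series with known ground truth.

The generator emulates two longitudinal sampling designs:

* a mouse repeat-pseudopregnancy cohort — daily blood-plasma progesterone
  over 26 weeks with a true oscillation period near 11 days, and
* a macaque menstrual-cycle cohort — progesterone sampled twice a week over
  9 weeks with a 32-day cycle,

plus immune-cell counts phase-locked to the hormone cycle, so that every
downstream stage (spectral estimation, waveform fitting, fold-change
statistics) can be tested against a known truth.

The clean hormone waveform is

    value(t) = baseline + amplitude * sin(2*pi*(t - phase_offset)/period + pi/2)

so the peak falls exactly at ``t = phase_offset`` (plus whole periods).
Noise is multiplicative log-normal by default (concentrations are positive
and right-skewed); the log-normal factor is mean-one, so noise does not
shift the expected level.  Additive Gaussian noise is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import TimeSeries

_NOISE_KINDS = ("lognormal", "gaussian")


@dataclass(frozen=True)
class HormoneCycleSpec:
    """Parameters of a synthetic hormone oscillation and its sampling design.

    Attributes
    ----------
    period : float
        True oscillation period in days (> 0).
    amplitude : float
        Peak deviation from baseline, concentration units (>= 0).
    baseline : float
        Mean concentration level (> 0).
    phase_offset : float
        Day at which the waveform peaks (peak also at phase_offset + k*period).
    noise_sigma : float
        Log-scale sigma for ``lognormal`` noise, or concentration-unit sigma
        for ``gaussian`` noise.  0 disables noise.
    noise_kind : str
        ``"lognormal"`` (multiplicative, mean-one) or ``"gaussian"`` (additive).
    sampling_days : tuple of float
        Ordered sampling times in days; duplicates allowed (assay replicates
        are treated downstream as independent observations).
    n_animals : int
        Cohort size.
    phase_jitter_sd : float
        SD (days) of a per-animal Gaussian jitter on phase_offset; 0 disables.
    seed : int
        Master seed; per-animal streams are spawned deterministically.
    analyte, units : str
        Labels carried into the output tables.
    """

    period: float
    amplitude: float
    baseline: float
    phase_offset: float = 0.0
    noise_sigma: float = 0.0
    noise_kind: str = "lognormal"
    sampling_days: tuple = ()
    n_animals: int = 1
    phase_jitter_sd: float = 0.0
    seed: int = 0
    analyte: str = "progesterone"
    units: str = "ng/mL"

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_kind not in _NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {_NOISE_KINDS}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        days = tuple(float(d) for d in self.sampling_days)
        if len(days) == 0:
            raise ValueError("sampling_days must be non-empty")
        if any(d < 0 for d in days):
            raise ValueError("sampling_days must be non-negative")
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be non-decreasing")
        object.__setattr__(self, "sampling_days", days)

    def clean_values(self, t: np.ndarray, phase_offset: float | None = None) -> np.ndarray:
        """Noise-free waveform evaluated at days ``t``."""
        phi0 = self.phase_offset if phase_offset is None else phase_offset
        t = np.asarray(t, dtype=float)
        ang = 2.0 * np.pi * (t - phi0) / self.period + 0.5 * np.pi
        return self.baseline + self.amplitude * np.sin(ang)

    def phase_angle(self, t: np.ndarray, phase_offset: float | None = None) -> np.ndarray:
        """Cycle phase angle at days ``t``; the hormone peak sits at pi/2."""
        phi0 = self.phase_offset if phase_offset is None else phase_offset
        t = np.asarray(t, dtype=float)
        return np.mod(2.0 * np.pi * (t - phi0) / self.period + 0.5 * np.pi, 2.0 * np.pi)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sampling_days"] = list(d["sampling_days"])
        return d


def _animal_rng(seed: int, n_animals: int, animal_index: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(n_animals)
    return np.random.default_rng(children[animal_index])


def generate_hormone_series(spec: HormoneCycleSpec, animal_index: int) -> TimeSeries:
    """Generate one animal's hormone series under ``spec``.

    The animal's random stream is spawned from the master seed, so series
    ``i`` of a cohort is identical whether generated alone or via
    :func:`generate_cohort`.
    """
    if not 0 <= animal_index < spec.n_animals:
        raise ValueError(
            f"animal_index {animal_index} out of range for n_animals={spec.n_animals}"
        )
    rng = _animal_rng(spec.seed, spec.n_animals, animal_index)
    phi0 = spec.phase_offset
    if spec.phase_jitter_sd > 0:
        phi0 = phi0 + rng.normal(0.0, spec.phase_jitter_sd)
    t = np.asarray(spec.sampling_days, dtype=float)
    clean = spec.clean_values(t, phase_offset=phi0)
    if spec.noise_sigma == 0:
        vals = clean
    elif spec.noise_kind == "lognormal":
        s = spec.noise_sigma
        # mean-one multiplicative factor: E[exp(N(-s^2/2, s^2))] = 1
        vals = clean * np.exp(rng.normal(-0.5 * s * s, s, size=t.size))
    else:
        vals = clean + rng.normal(0.0, spec.noise_sigma, size=t.size)
    return TimeSeries(
        animal_id=f"animal_{animal_index:02d}",
        times=t,
        values=vals,
        analyte=spec.analyte,
        units=spec.units,
    )


def generate_cohort(spec: HormoneCycleSpec) -> list[TimeSeries]:
    """Generate the full cohort of ``spec.n_animals`` series."""
    return [generate_hormone_series(spec, i) for i in range(spec.n_animals)]


@dataclass(frozen=True)
class ImmuneCountSpec:
    """Parameters of phase-locked synthetic immune-cell counts.

    Counts follow a negative binomial whose mean tracks the hormone cycle:
    ``mean(t) = baseline_count * fold(theta(t))`` with the cosine
    interpolation ``fold(theta) = 1 + (fold_amplitude - 1) *
    (1 + cos(theta - peak_angle)) / 2``, i.e. fold 1 at antiphase and
    ``fold_amplitude`` at ``peak_angle``.  ``fold_amplitude`` < 1 models a
    depletion rather than an enrichment.  ``dispersion`` is the negative
    binomial size parameter (variance = mean + mean^2/dispersion); very
    large values approach Poisson counts.
    """

    population: str
    baseline_count: float
    fold_amplitude: float
    peak_angle: float
    dispersion: float
    hormone: HormoneCycleSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_count < 0:
            raise ValueError("baseline_count must be >= 0")
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if not 0 <= self.peak_angle < 2 * math.pi:
            raise ValueError("peak_angle must lie in [0, 2*pi)")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")

    def true_fold(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return 1.0 + (self.fold_amplitude - 1.0) * 0.5 * (
            1.0 + np.cos(theta - self.peak_angle)
        )


def generate_immune_counts(
    ispec: ImmuneCountSpec,
    sampling_days,
    n_animals: int | None = None,
) -> pd.DataFrame:
    """Draw phase-locked immune counts for a cohort.

    Returns a tidy table with columns ``animal_id, day, population, count``
    plus the ground-truth columns ``phase_angle`` and ``true_fold`` used by
    recovery tests.
    """
    hspec = ispec.hormone
    n_animals = hspec.n_animals if n_animals is None else int(n_animals)
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    t = np.asarray(list(sampling_days), dtype=float)
    if t.size == 0:
        raise ValueError("sampling_days must be non-empty")
    theta = hspec.phase_angle(t)
    fold = ispec.true_fold(theta)
    mean = ispec.baseline_count * fold
    children = np.random.SeedSequence(ispec.seed).spawn(n_animals)
    frames = []
    for i in range(n_animals):
        rng = np.random.default_rng(children[i])
        counts = np.zeros(t.size, dtype=np.int64)
        pos = mean > 0
        if np.any(pos):
            k = ispec.dispersion
            p = k / (k + mean[pos])
            counts[pos] = rng.negative_binomial(k, p)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": f"animal_{i:02d}",
                    "day": t,
                    "population": ispec.population,
                    "count": counts,
                    "phase_angle": theta,
                    "true_fold": fold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_deg_table(n_genes: int, n_true: int, seed: int = 0) -> pd.DataFrame:
    """Differential-expression fixture with planted significant genes.

    Exactly ``n_true`` rows satisfy the strict significance rule
    FDR < 0.05 and \\|log2FC\\| > 1; every other row fails at least one of
    the two thresholds.  Columns: ``gene, log2FC, FDR``.
    """
    if not 0 <= n_true <= n_genes:
        raise ValueError("need 0 <= n_true <= n_genes")
    rng = np.random.default_rng(seed)
    log2fc = np.empty(n_genes)
    fdr = np.empty(n_genes)
    # planted positives: strictly inside both thresholds
    signs = rng.choice([-1.0, 1.0], size=n_true)
    log2fc[:n_true] = signs * rng.uniform(1.05, 5.0, size=n_true)
    fdr[:n_true] = rng.uniform(1e-4, 0.045, size=n_true)
    # negatives: fail fdr, fail fold change, or fail both
    n_null = n_genes - n_true
    mode = rng.integers(0, 3, size=n_null)
    lfc_pass = rng.choice([-1.0, 1.0], size=n_null) * rng.uniform(1.05, 5.0, size=n_null)
    lfc_fail = rng.choice([-1.0, 1.0], size=n_null) * rng.uniform(0.0, 0.95, size=n_null)
    fdr_pass = rng.uniform(1e-4, 0.045, size=n_null)
    fdr_fail = rng.uniform(0.05, 1.0, size=n_null)
    log2fc[n_true:] = np.where(mode == 1, lfc_pass, lfc_fail)
    fdr[n_true:] = np.where(mode == 0, fdr_pass, fdr_fail)
    df = pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_genes)],
            "log2FC": log2fc,
            "FDR": fdr,
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def mouse_preset(seed: int = 0, **overrides) -> HormoneCycleSpec:
    """Repeat-pseudopregnancy mouse cohort: daily progesterone over 26 weeks,
    true period 11 d, peak at day 6 of the cycle, 3 animals."""
    params = dict(
        period=11.0,
        amplitude=8.0,
        baseline=10.0,
        phase_offset=6.0,
        noise_sigma=0.2,
        noise_kind="lognormal",
        sampling_days=tuple(float(d) for d in range(182)),
        n_animals=3,
        seed=seed,
        analyte="progesterone",
        units="ng/mL",
    )
    params.update(overrides)
    return HormoneCycleSpec(**params)


def macaque_preset(seed: int = 0, **overrides) -> HormoneCycleSpec:
    """Pig-tailed macaque cohort: progesterone sampled twice a week
    (alternating 3/4-day gaps) over 9 weeks, 32-day cycle, 6 animals."""
    days = []
    d = 0.0
    step = (3.0, 4.0)
    i = 0
    while d <= 63.0:
        days.append(d)
        d += step[i % 2]
        i += 1
    params = dict(
        period=32.0,
        amplitude=3.5,
        baseline=5.0,
        phase_offset=20.0,
        noise_sigma=0.2,
        noise_kind="lognormal",
        sampling_days=tuple(days),
        n_animals=6,
        seed=seed,
        analyte="progesterone",
        units="ng/mL",
    )
    params.update(overrides)
    return HormoneCycleSpec(**params)


PRESETS = {
    "mouse-pseudopregnancy": mouse_preset,
    "macaque": macaque_preset,
}
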