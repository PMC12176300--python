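"""Sinusoid waveform reconstruction and cycle-phase mapping across species.

A fitted waveform ``A*sin(2*pi*f*t) + B*cos(2*pi*f*t) + C`` is summarized by
amplitude ``R = sqrt(A^2 + B^2)`` and phase offset ``phi = atan2(B, A)``, so
the reconstruction is identically ``R*sin(2*pi*f*t + phi) + C``.  The phase
angle of a day is

    theta(t) = (2*pi*f*t + phi) mod 2*pi,

which places the waveform peak exactly at ``theta = pi/2`` and the trough at
``3*pi/2`` — the convention used to label hormone cycles (e.g. the macaque
luteal phase as an angular window).  Day and angle interconvert at the
uniform rate ``2*pi/T``; a named cycle stage can therefore be carried from
one species' fitted cycle to another's through its angular window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .series import TimeSeries
from .spectral import PeriodogramPeak, ls_fit_at_frequency

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SinusoidFit:
    """Fitted sinusoid at a fixed frequency, with derived amplitude/phase."""

    frequency: float
    A: float
    B: float
    C: float
    fit_domain: tuple[float, float] = (0.0, 0.0)
    power: float | None = None

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def amplitude(self) -> float:
        """R = sqrt(A^2 + B^2) >= 0."""
        return math.hypot(self.A, self.B)

    @property
    def phase_offset(self) -> float:
        """phi = atan2(B, A), radians."""
        return math.atan2(self.B, self.A)

    def predict(self, t) -> np.ndarray:
        """Reconstructed waveform A*sin(2*pi*f*t) + B*cos(2*pi*f*t) + C."""
        t = np.asarray(t, dtype=float)
        w = _TWO_PI * self.frequency * t
        return self.A * np.sin(w) + self.B * np.cos(w) + self.C

    @property
    def peak_day(self) -> float:
        """First non-negative day at which the waveform peaks (theta = pi/2)."""
        return day_at_angle(self, 0.5 * math.pi)

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "period": self.period,
            "A": self.A,
            "B": self.B,
            "C": self.C,
            "amplitude": self.amplitude,
            "phase_offset": self.phase_offset,
            "fit_domain": list(self.fit_domain),
            "power": self.power,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SinusoidFit":
        return cls(
            frequency=float(d["frequency"]),
            A=float(d["A"]),
            B=float(d["B"]),
            C=float(d["C"]),
            fit_domain=tuple(d.get("fit_domain", (0.0, 0.0))),
            power=d.get("power"),
        )


def fit_waveform(ts: TimeSeries, peak: PeriodogramPeak) -> SinusoidFit:
    """Least-squares sinusoid at the dominant frequency of ``ts``.

    Expects a mean-normalized series (so C is near 1 and the amplitude is a
    fold-like displacement), though the fit itself imposes nothing.
    """
    fit = ls_fit_at_frequency(ts, peak.frequency)
    return SinusoidFit(
        frequency=peak.frequency,
        A=fit.A,
        B=fit.B,
        C=fit.C,
        fit_domain=(float(ts.times[0]), float(ts.times[-1])),
        power=fit.power,
    )


def _require_oscillation(fit: SinusoidFit) -> None:
    if fit.amplitude <= 0:
        raise ValueError("fit has zero amplitude; phase is undefined")


def phase_angle(fit: SinusoidFit, t) -> np.ndarray | float:
    """Cycle phase angle theta(t) = (2*pi*f*t + phi) mod 2*pi.

    The reconstructed waveform attains its maximum C + R at theta = pi/2 and
    its minimum C - R at theta = 3*pi/2.
    """
    _require_oscillation(fit)
    t_arr = np.asarray(t, dtype=float)
    theta = np.mod(_TWO_PI * fit.frequency * t_arr + fit.phase_offset, _TWO_PI)
    return float(theta) if np.isscalar(t) or t_arr.ndim == 0 else theta


def day_at_angle(fit: SinusoidFit, theta: float) -> float:
    """Inverse of :func:`phase_angle` on one cycle: the day in [0, T) at
    which the phase angle equals ``theta``."""
    _require_oscillation(fit)
    d = float(np.mod(theta - fit.phase_offset, _TWO_PI) / (_TWO_PI * fit.frequency))
    # float round-off in mod can land exactly on T; identify with day 0
    return 0.0 if d >= fit.period else d


@dataclass(frozen=True)
class PhaseWindow:
    """A named cycle stage as an angular interval.

    ``angle_start`` lies in [0, 2*pi); ``angle_end`` may exceed 2*pi to
    represent a window wrapping past the origin.  Window length is in
    (0, 2*pi].
    """

    name: str
    angle_start: float
    angle_end: float

    def __post_init__(self) -> None:
        if not 0 <= self.angle_start < _TWO_PI:
            raise ValueError("angle_start must lie in [0, 2*pi)")
        length = self.angle_end - self.angle_start
        if not 0 < length <= _TWO_PI + 1e-12:
            raise ValueError("window length must lie in (0, 2*pi]")

    @property
    def length(self) -> float:
        return self.angle_end - self.angle_start

    def contains(self, theta) -> np.ndarray | bool:
        """Membership of angle(s) in the window on the circle
        (start inclusive, end exclusive; a full-circle window contains all)."""
        theta = np.asarray(theta, dtype=float)
        rel = np.mod(theta - self.angle_start, _TWO_PI)
        if self.length >= _TWO_PI - 1e-12:
            out = np.ones_like(rel, dtype=bool)
        else:
            out = rel < self.length
        return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DayWindow:
    """A named cycle stage as a day interval within a cycle of given length.

    ``day_start`` lies in [0, cycle_length); ``day_end`` may exceed
    ``cycle_length`` for a window wrapping past day 0 — :meth:`split` breaks
    such a window into in-cycle segments for serialization.
    """

    name: str
    day_start: float
    day_end: float
    cycle_length: float

    def __post_init__(self) -> None:
        if not self.cycle_length > 0:
            raise ValueError("cycle_length must be positive")
        if not 0 <= self.day_start < self.cycle_length:
            raise ValueError("day_start must lie in [0, cycle_length)")
        width = self.day_end - self.day_start
        if not 0 < width <= self.cycle_length + 1e-12:
            raise ValueError("window width must lie in (0, cycle_length]")

    @property
    def width(self) -> float:
        return self.day_end - self.day_start

    def split(self) -> list[tuple[float, float]]:
        """Segments of the window clipped to [0, cycle_length]."""
        if self.day_end <= self.cycle_length:
            return [(self.day_start, self.day_end)]
        return [
            (self.day_start, self.cycle_length),
            (0.0, self.day_end - self.cycle_length),
        ]


def day_window_to_phase(fit: SinusoidFit, dw: DayWindow) -> PhaseWindow:
    """Map a day interval to an angular window via the fitted cycle.

    The angular rate is the uniform 2*pi/T of the fit; a mismatch of more
    than 20% between the window's nominal cycle length and the fitted
    period is reported as a warning, not an error.
    """
    _require_oscillation(fit)
    if abs(dw.cycle_length - fit.period) > 0.2 * fit.period:
        warnings.warn(
            f"window {dw.name!r} declares cycle_length={dw.cycle_length:.3g} d "
            f"but the fit's period is {fit.period:.3g} d",
            stacklevel=2,
        )
    start = phase_angle(fit, dw.day_start)
    length = _TWO_PI * dw.width / fit.period
    if length > _TWO_PI + 1e-12:
        raise ValueError("day window spans more than one fitted cycle")
    return PhaseWindow(name=dw.name, angle_start=start, angle_end=start + min(length, _TWO_PI))


def phase_to_day_window(fit: SinusoidFit, pw: PhaseWindow) -> DayWindow:
    """Map an angular window onto days of the fitted cycle (inverse of
    :func:`day_window_to_phase` on one cycle)."""
    _require_oscillation(fit)
    start = day_at_angle(fit, pw.angle_start)
    width = pw.length * fit.period / _TWO_PI
    return DayWindow(
        name=pw.name,
        day_start=start,
        day_end=start + width,
        cycle_length=fit.period,
    )


def align_species(
    fit_source: SinusoidFit,
    windows_source: list[DayWindow],
    fit_target: SinusoidFit,
) -> list[DayWindow]:
    """Carry named day windows from one species' cycle onto another's.

    Each window travels through its angular representation: day window →
    phase window on the source fit → day window on the target fit.  Order
    and non-overlap on the circle are preserved; widths scale by
    T_target / T_source.
    """
    return [
        phase_to_day_window(fit_target, day_window_to_phase(fit_source, dw))
        for dw in windows_source
    ]


def assign_phase_labels(
    angles,
    windows: list[PhaseWindow],
    default: str = "other",
) -> list[str]:
    """Label each phase angle with the first window containing it."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    labels = [default] * angles.size
    for i, theta in enumerate(angles):
        for w in windows:
            if w.contains(theta):
                labels[i] = w.name
                break
    return labels
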