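"""Containers and tidy-table I/O for irregularly sampled analyte series.

A :class:`TimeSeries` holds one animal's trajectory of a single analyte
(e.g. blood-plasma progesterone) sampled at arbitrary, possibly duplicated,
day values.  Tidy long-format tables use the columns
``animal_id, day, analyte, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TIDY_COLUMNS = ("animal_id", "day", "analyte", "value")


class DegenerateSeriesError(ValueError):
    """Raised when a series cannot support the requested operation
    (constant values, zero mean, or too few distinct time points)."""


@dataclass(frozen=True)
class TimeSeries:
    """One animal's irregularly sampled analyte trajectory.

    Parameters
    ----------
    animal_id : str
        Animal label.
    times : array-like of float
        Sampling times in days; finite, non-negative, non-decreasing.
        Duplicate days are allowed and treated as independent observations.
    values : array-like of float
        Measured concentrations, same length as ``times``.
    analyte : str
        Analyte label, e.g. ``"progesterone"``.
    units : str
        Concentration units (label only; never used in computation).
    """

    animal_id: str
    times: np.ndarray
    values: np.ndarray
    analyte: str = "progesterone"
    units: str = "ng/mL"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.size != v.size:
            raise ValueError(
                f"times ({t.size}) and values ({v.size}) differ in length"
            )
        if t.size == 0:
            raise ValueError("series must contain at least one observation")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("times and values must be finite")
        if np.any(t < 0):
            raise ValueError("times must be non-negative days")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        t.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Time span max(times) − min(times) in days."""
        return float(self.times[-1] - self.times[0])

    @property
    def n_distinct_times(self) -> int:
        return int(np.unique(self.times).size)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view of this series."""
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "day": self.times,
                "analyte": self.analyte,
                "value": self.values,
            }
        )


def validate_tidy(df: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy hormone table for the required columns and finite values."""
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy table is missing columns: {missing}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("tidy table contains non-finite values")
    return df


def series_from_tidy(
    df: pd.DataFrame,
    animal_id: str,
    analyte: str,
    units: str = "ng/mL",
) -> TimeSeries:
    """Extract one (animal, analyte) series from a tidy table, sorted by day."""
    validate_tidy(df)
    sel = df[(df["animal_id"].astype(str) == str(animal_id)) & (df["analyte"] == analyte)]
    if sel.empty:
        raise KeyError(f"no rows for animal_id={animal_id!r}, analyte={analyte!r}")
    sel = sel.sort_values("day", kind="stable")
    return TimeSeries(
        animal_id=str(animal_id),
        times=sel["day"].to_numpy(dtype=float),
        values=sel["value"].to_numpy(dtype=float),
        analyte=analyte,
        units=units,
    )


def cohort_to_tidy(series: list[TimeSeries]) -> pd.DataFrame:
    """Concatenate per-animal series into one tidy long table."""
    if not series:
        return pd.DataFrame(columns=list(TIDY_COLUMNS))
    return pd.concat([s.to_frame() for s in series], ignore_index=True)
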