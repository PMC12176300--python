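"""Shared fixtures and independent oracles.

The brute-force oracle solves the three-parameter sinusoid fit directly
from the design matrix with a dense lstsq, independent of the package's
batched normal-equations path, and is the reference for periodogram power.
"""

import numpy as np
import pytest


def brute_force_sinusoid_fit(times, values, f):
    """Direct least-squares solve of y ~ A sin(2pi f t) + B cos(2pi f t) + C.

    Returns (beta, power) with power = 1 - SSR/SSR0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    w = 2.0 * np.pi * f * t
    X = np.column_stack([np.sin(w), np.cos(w), np.ones_like(t)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ beta) ** 2))
    ssr0 = float(np.sum((y - y.mean()) ** 2))
    return beta, 1.0 - ssr / ssr0


@pytest.fixture
def brute_power():
    def _power(times, values, f):
        return brute_force_sinusoid_fit(times, values, f)[1]

    return _power


@pytest.fixture
def brute_fit():
    return brute_force_sinusoid_fit


@pytest.fixture
def six_point_series():
    """Small irregular series used across spectral/waveform oracle checks."""
    from cyclescope import TimeSeries

    return TimeSeries(
        animal_id="m0",
        times=np.array([0.0, 1.0, 2.0, 4.0, 7.0, 9.0]),
        values=np.array([1.2, 0.7, 0.4, 1.5, 0.2, 1.1]),
    )
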