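"""Sliding-average filter with finite-difference phase reconstruction.

The simplest sequential smoother: estimate the position as a centered
moving mean of n observations,

    p_i = (1/n) sum_{j=i-(n-1)/2}^{i+(n-1)/2} P_j,

then reconstruct velocity and acceleration by forward differencing,

    v_i = (p_{i+1} - p_i) / dt,    a_i = (v_{i+1} - v_i) / dt.

This serves as the comparison baseline for the shadowing filter.  Double
differencing amplifies observation noise by a factor of order 1/dt^4 in
variance, producing the characteristic acceleration spikes, and the
centered mean attenuates turning points; both effects are quantified in
the test suite.  Edges where the averaging window overhangs the series are
truncated (no padding), so an m-sample series yields m - (n-1) positions,
one fewer velocities and two fewer accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .exceptions import InvalidInputError
from .tracks import ObservationSeries

__all__ = [
    "BaselineResult",
    "sliding_average",
    "finite_difference_phase",
    "sliding_baseline",
    "SlidingAverageFilter",
]


@dataclass(frozen=True)
class BaselineResult:
    """Phase-space estimate from the sliding-average baseline.

    ``velocities`` is one entry shorter than ``positions`` and
    ``accelerations`` two shorter (forward differences, truncated edges).
    ``times`` are the sample times of ``positions``.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    window: int
    dt: float


def _regular_dt(times: np.ndarray) -> float:
    steps = np.diff(times)
    if steps.size == 0:
        raise InvalidInputError("need at least 2 samples")
    dt = float(steps[0])
    if np.any(np.abs(steps - dt) > 1e-9 * abs(dt)):
        raise InvalidInputError(
            "sliding average requires a regular time grid; for irregular "
            "sampling use the shadowing filter instead")
    return dt


def sliding_average(obs, window: int, times=None) -> np.ndarray:
    """Centered moving mean of the positions.

    ``obs`` may be an :class:`ObservationSeries` (whose grid must be
    regular) or a plain array with ``times`` supplied separately (or
    omitted, in which case regularity is assumed).  The window must be odd
    and no longer than the series; the output drops ``(window-1)/2``
    samples at each edge.
    """
    if isinstance(obs, ObservationSeries):
        values = obs.values
        times = obs.times
    else:
        values = np.asarray(obs, dtype=float)
    if times is not None:
        _regular_dt(np.asarray(times, dtype=float))
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise InvalidInputError("window must be odd and >= 1")
    m = values.shape[0]
    if window > m:
        raise InvalidInputError("window longer than the series")
    kernel = np.ones(window) / window
    if values.ndim == 1:
        return np.convolve(values, kernel, mode="valid")
    return np.column_stack([
        np.convolve(values[:, k], kernel, mode="valid")
        for k in range(values.shape[1])
    ])


def finite_difference_phase(positions, dt: float):
    """Forward-difference velocity and acceleration from positions.

    Returns ``(velocities, accelerations)`` with lengths m-1 and m-2.
    """
    positions = np.asarray(positions, dtype=float)
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if positions.shape[0] < 3:
        raise InvalidInputError("need at least 3 positions to differentiate")
    velocities = np.diff(positions, axis=0) / dt
    accelerations = np.diff(velocities, axis=0) / dt
    return velocities, accelerations


def sliding_baseline(obs: ObservationSeries, window: int = 5) -> BaselineResult:
    """Sliding-average smoothing followed by double differencing."""
    dt = _regular_dt(obs.times)
    positions = sliding_average(obs, window)
    if positions.shape[0] < 3:
        raise InvalidInputError("series too short for the requested window")
    velocities, accelerations = finite_difference_phase(positions, dt)
    half = (window - 1) // 2
    times = obs.times[half:obs.n_samples - half]
    return BaselineResult(times=times, positions=positions,
                          velocities=velocities,
                          accelerations=accelerations,
                          window=window, dt=dt)


class SlidingAverageFilter(BaseEstimator):
    """Sliding-average baseline as a scikit-learn style estimator.

    Parameters
    ----------
    window : int, default 5
        Odd averaging window length in samples.

    Attributes
    ----------
    positions_, velocities_, accelerations_ : ndarray
        Smoothed positions and their forward differences (lengths shrink
        by one per differentiation).
    times_ : ndarray
        Sample times of ``positions_``.
    dt_ : float
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None, *, times=None):
        X = np.asarray(X, dtype=float)
        if times is None:
            times = np.arange(X.shape[0], dtype=float)
        obs = ObservationSeries(times, X)
        res = sliding_baseline(obs, self.window)
        self.result_ = res
        self.times_ = res.times
        self.positions_ = res.positions
        self.velocities_ = res.velocities
        self.accelerations_ = res.accelerations
        self.dt_ = res.dt
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).positions_

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise NotFittedError("SlidingAverageFilter is not fitted yet")
        return self.positions_
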