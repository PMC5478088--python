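"""Synthetic Newtonian tracks and GPS-like observations.

Generates ground-truth trajectories with piecewise-constant per-interval
accelerations and observations that emulate avian GPS telemetry: 0.2 s
sampling, isotropic Gaussian fix noise of variance ~0.4 m^2 per
coordinate, and ~36% of fixes missing (device dropouts).  Accelerations
stay within the few-m/s^2 envelope typical of pigeon flight, and flight
segments are defined by speed exceeding 4 m/s.

Acceleration models
-------------------
piecewise_constant
    i.i.d. uniform(-scale, scale) acceleration per interval: the roughest
    track the filter's model class contains.
smooth_random
    Gaussian white noise smoothed over a ~1 s kernel and scaled to RMS
    scale/2: a maneuvering, turning flight.
circular
    Planar loop at exactly constant speed (free-flight pattern), built as
    an exact discrete rotation so that the piecewise-constant-acceleration
    recursions hold to machine precision.
sinusoid
    Per-coordinate sinusoidal weaving with random phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import InvalidInputError
from .tracks import ObservationSeries, PhaseTrajectory, newton_propagate

__all__ = [
    "SyntheticSpec",
    "simulate_true_track",
    "observe",
    "decimate",
    "segment_flight",
]

_MODELS = ("piecewise_constant", "smooth_random", "circular", "sinusoid")

#: flight/non-flight speed threshold (m/s)
FLIGHT_SPEED_THRESHOLD = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic experiment.

    Parameters
    ----------
    duration : float
        Track duration in seconds.
    dt : float
        Sampling interval (s); 0.2 s matches the GPS logging rate.
    accel_model : str
        One of ``piecewise_constant``, ``smooth_random``, ``circular``,
        ``sinusoid``.
    accel_scale : float
        Acceleration magnitude scale (m/s^2); the default 4.0 sits inside
        the +/-8 m/s^2 envelope of recorded pigeon flight.
    noise_variance : float
        Observation noise variance beta per coordinate (m^2); default the
        0.4 m^2 device error variance.
    missing_fraction : float
        Fraction of fixes flagged as device dropouts (default 0.36).
    dims : int
        1-3 coordinates; flight is essentially planar, so 2 by default.
    seed : int
        Seed for all randomness in the generator.
    speed : float
        Cruise speed for the circular model (m/s); 10 m/s is a typical
        pigeon flight speed.
    frequency : float
        Weave frequency for the sinusoid model (Hz).
    """

    duration: float = 30.0
    dt: float = 0.2
    accel_model: str = "smooth_random"
    accel_scale: float = 4.0
    noise_variance: float = 0.4
    missing_fraction: float = 0.36
    dims: int = 2
    seed: int = 0
    speed: float = 10.0
    frequency: float = 0.2

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidInputError("duration and dt must be positive")
        if not (0 <= self.missing_fraction < 1):
            raise InvalidInputError("missing_fraction must lie in [0, 1)")
        if self.accel_model not in _MODELS:
            raise InvalidInputError(
                f"accel_model must be one of {_MODELS}")
        if not (1 <= self.dims <= 3):
            raise InvalidInputError("dims must be 1, 2 or 3")
        if self.noise_variance < 0 or self.accel_scale < 0:
            raise InvalidInputError(
                "noise_variance and accel_scale must be >= 0")


def _time_grid(spec: SyntheticSpec) -> np.ndarray:
    m = int(round(spec.duration / spec.dt)) + 1
    return np.arange(m) * spec.dt


def simulate_true_track(spec: SyntheticSpec) -> PhaseTrajectory:
    """Generate a Newton-consistent ground-truth trajectory."""
    times = _time_grid(spec)
    m = times.size
    rng = np.random.default_rng(spec.seed)
    d = spec.dims
    zero = _squeeze(np.zeros(d), d)
    if spec.accel_model == "piecewise_constant":
        a = rng.uniform(-spec.accel_scale, spec.accel_scale, size=(m - 1, d))
        return newton_propagate(zero, zero, _squeeze(a, d), times)
    if spec.accel_model == "smooth_random":
        white = rng.standard_normal((m - 1, d))
        sigma_samples = max(1.0, 1.0 / spec.dt)  # ~1 s correlation time
        a = gaussian_filter1d(white, sigma_samples, axis=0, mode="nearest")
        std = a.std(axis=0)
        std[std == 0] = 1.0
        a = a / std * (spec.accel_scale / 2.0)
        return newton_propagate(zero, zero, _squeeze(a, d), times)
    if spec.accel_model == "circular":
        return _circular_track(spec, times)
    # sinusoid: per-dim A sin(2 pi f t + phi); accelerations sampled at
    # interval midpoints, then propagated from the exact initial state
    f = spec.frequency
    omega = 2 * np.pi * f
    A = spec.accel_scale / omega**2
    phi = rng.uniform(0, 2 * np.pi, size=d)
    mid = 0.5 * (times[:-1] + times[1:])
    a = -A * omega**2 * np.sin(omega * mid[:, None] + phi[None, :])
    p0 = A * np.sin(phi)
    v0 = A * omega * np.cos(phi)
    return newton_propagate(_squeeze(p0, d), _squeeze(v0, d),
                            _squeeze(a, d), times)


def _squeeze(arr: np.ndarray, d: int) -> np.ndarray:
    return arr[..., 0] if d == 1 else arr


def _circular_track(spec: SyntheticSpec, times: np.ndarray) -> PhaseTrajectory:
    """Exact discrete circular motion.

    With angle step delta = omega*dt per interval, placing positions on the
    circle and giving velocities the tangential magnitude
    (2R/dt) tan(delta/2) makes the constant-acceleration recursions exact:
    the chord equals dt*(v_i + v_{i+1})/2.  Speed is constant exactly, and
    each interval acceleration is orthogonal to the interval's mean
    velocity (discrete centripetality).
    """
    if spec.dims < 2:
        raise InvalidInputError("circular model needs dims >= 2")
    if spec.accel_scale <= 0:
        raise InvalidInputError("circular model needs accel_scale > 0")
    R = spec.speed**2 / spec.accel_scale
    omega = spec.accel_scale / spec.speed
    dt = spec.dt
    theta = omega * times
    vmag = (2.0 * R / dt) * np.tan(omega * dt / 2.0)
    p = np.zeros((times.size, spec.dims))
    v = np.zeros((times.size, spec.dims))
    p[:, 0] = R * np.cos(theta)
    p[:, 1] = R * np.sin(theta)
    v[:, 0] = -vmag * np.sin(theta)
    v[:, 1] = vmag * np.cos(theta)
    a = np.diff(v, axis=0) / dt
    return PhaseTrajectory(times, p, v, a)


def observe(truth: PhaseTrajectory, spec: SyntheticSpec,
            drop_invalid: bool = False) -> ObservationSeries:
    """GPS-like observations of a true trajectory.

    Adds i.i.d. Gaussian noise of variance ``spec.noise_variance`` per
    coordinate and flags a seeded random subset of
    ``floor(missing_fraction * N)`` samples as invalid (device dropouts);
    with ``drop_invalid`` those samples are removed instead of flagged.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    values = truth.positions + rng.normal(
        0.0, np.sqrt(spec.noise_variance), size=truth.positions.shape)
    m = truth.n_samples
    n_missing = int(np.floor(spec.missing_fraction * m))
    flags = np.ones(m, dtype=bool)
    if n_missing:
        flags[rng.choice(m, size=n_missing, replace=False)] = False
    obs = ObservationSeries(truth.times, values, valid_flags=flags)
    return obs.drop_invalid() if drop_invalid else obs


def decimate(obs: ObservationSeries, factor: int) -> ObservationSeries:
    """Keep every factor-th sample starting at index 0."""
    factor = int(factor)
    if factor < 1:
        raise InvalidInputError("decimation factor must be >= 1")
    return obs.take(np.arange(0, obs.n_samples, factor))


def segment_flight(speeds, threshold: float = FLIGHT_SPEED_THRESHOLD
                   ) -> List[Tuple[int, int]]:
    """Flight segments: maximal runs with speed strictly above threshold.

    Returns half-open index intervals [start, end).  The criterion is
    exclusive: a sample at exactly the threshold is non-flight.
    """
    speeds = np.asarray(speeds, dtype=float)
    if not np.all(np.isfinite(speeds)):
        raise InvalidInputError("speeds must be finite")
    mask = speeds > threshold
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]
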