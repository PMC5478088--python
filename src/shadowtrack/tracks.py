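"""Observation series and Newton-consistent phase trajectories.

The dynamical model throughout the package is piecewise-constant
acceleration: within each sampling interval ``[t_i, t_{i+1})`` the
acceleration ``a_i`` is a constant, so position and velocity obey

    p_{i+1} = p_i + v_i * T_i + a_i * T_i**2 / 2
    v_{i+1} = v_i + a_i * T_i

with ``T_i = t_{i+1} - t_i > 0``.  :class:`PhaseTrajectory` enforces these
recursions as a type invariant; :func:`newton_propagate` is the canonical
constructor.  :class:`ObservationSeries` holds the noisy position fixes
``P_i`` together with per-fix error variances ``sigma_i**2`` and validity
flags (flag 0 marks a fix that was interpolated rather than logged by the
device).

All quantities are SI: seconds, meters, m/s, m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "ObservationSeries",
    "PhaseTrajectory",
    "newton_propagate",
    "rms_error",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite")
    return arr


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1:
        raise InvalidInputError("times must be one-dimensional")
    if times.size >= 2:
        dt = np.diff(times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise InvalidInputError(
                f"times must be strictly increasing; first offending row {row} "
                f"(t={times[row]!r} after t={times[row - 1]!r})"
            )


# interval T_i broadcast against (m,) or (m, d) sample arrays
def _col(T: np.ndarray, like: np.ndarray) -> np.ndarray:
    return T if like.ndim == 1 else T[:, None]


@dataclass(frozen=True)
class ObservationSeries:
    """Time-stamped noisy position samples.

    Parameters
    ----------
    times : array, shape (m,)
        Sample times in seconds, strictly increasing.
    values : array, shape (m,) or (m, d)
        Observed positions in meters; one column per coordinate.
    error_variances : array, shape (m,), optional
        Observational error variance per sample (m^2), strictly positive.
        Default all 1.0.
    valid_flags : bool array, shape (m,), optional
        True for device-logged fixes, False for interpolated ones.
        Default all True.
    """

    times: np.ndarray
    values: np.ndarray
    error_variances: np.ndarray = None
    valid_flags: np.ndarray = None

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        values = _as_float_array(self.values, "values")
        _check_times(times)
        if values.ndim not in (1, 2):
            raise InvalidInputError("values must have shape (m,) or (m, d)")
        if values.shape[0] != times.size:
            raise InvalidInputError("values and times lengths differ")
        if self.error_variances is None:
            var = np.ones(times.size)
        else:
            var = _as_float_array(self.error_variances, "error_variances")
        if var.shape != (times.size,):
            raise InvalidInputError("error_variances length differs from times")
        if np.any(var <= 0):
            raise InvalidInputError("error_variances must be strictly positive")
        if self.valid_flags is None:
            flags = np.ones(times.size, dtype=bool)
        else:
            flags = np.asarray(self.valid_flags, dtype=bool)
        if flags.shape != (times.size,):
            raise InvalidInputError("valid_flags length differs from times")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "error_variances", var)
        object.__setattr__(self, "valid_flags", flags)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_dims(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def coordinate(self, k: int) -> "ObservationSeries":
        """Scalar series for coordinate ``k`` on the shared time grid."""
        vals = self.values if self.values.ndim == 1 else self.values[:, k]
        if self.values.ndim == 1 and k != 0:
            raise InvalidInputError("scalar series has only coordinate 0")
        return ObservationSeries(self.times, vals, self.error_variances,
                                 self.valid_flags)

    def take(self, index) -> "ObservationSeries":
        """Sub-series at the given sample indices (order preserved)."""
        idx = np.asarray(index)
        return ObservationSeries(self.times[idx], self.values[idx],
                                 self.error_variances[idx],
                                 self.valid_flags[idx])

    def drop_invalid(self) -> "ObservationSeries":
        """Remove samples whose validity flag is 0 (interpolated fixes)."""
        return self.take(np.flatnonzero(self.valid_flags))


@dataclass(frozen=True)
class PhaseTrajectory:
    """Reconstructed trajectory: positions, velocities and per-interval
    accelerations, Newton-consistent by construction.

    ``accelerations[i]`` is the constant acceleration on ``[t_i, t_{i+1})``,
    so there are ``m - 1`` acceleration entries for ``m`` samples.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray

    #: absolute Newton-consistency tolerance, scaled by max(1, |p|_max)
    _ATOL = 1e-9

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        p = _as_float_array(self.positions, "positions")
        v = _as_float_array(self.velocities, "velocities")
        a = _as_float_array(self.accelerations, "accelerations")
        _check_times(times)
        m = times.size
        if p.shape[0] != m or v.shape != p.shape:
            raise InvalidInputError("positions/velocities shapes inconsistent")
        if a.shape[0] != m - 1 or a.shape[1:] != p.shape[1:]:
            raise InvalidInputError(
                "accelerations must have one entry per interval")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "accelerations", a)
        self.validate()

    def validate(self) -> None:
        """Check the Newtonian recursions; raise on violation."""
        T = np.diff(self.times)
        Tc = _col(T, self.positions)
        p, v, a = self.positions, self.velocities, self.accelerations
        res_p = p[1:] - (p[:-1] + v[:-1] * Tc + 0.5 * a * Tc**2)
        res_v = v[1:] - (v[:-1] + a * Tc)
        scale = max(1.0, float(np.max(np.abs(p))) if p.size else 1.0)
        atol = self._ATOL * scale
        worst = max(float(np.max(np.abs(res_p))) if res_p.size else 0.0,
                    float(np.max(np.abs(res_v))) if res_v.size else 0.0)
        if worst > atol:
            raise InvalidInputError(
                f"trajectory violates Newton consistency: residual {worst:g} "
                f"exceeds tolerance {atol:g}")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_dims(self) -> int:
        return 1 if self.positions.ndim == 1 else self.positions.shape[1]

    @property
    def accelerations_per_sample(self) -> np.ndarray:
        """Per-sample acceleration: interval value assigned to its left
        endpoint, final sample repeating the last interval."""
        a = self.accelerations
        if a.shape[0] == 0:
            return np.zeros_like(self.positions)
        return np.concatenate([a, a[-1:]], axis=0)

    @property
    def speeds(self) -> np.ndarray:
        """Euclidean velocity magnitude per sample."""
        v = self.velocities
        return np.abs(v) if v.ndim == 1 else np.sqrt(np.sum(v**2, axis=1))


def newton_propagate(p0, v0, accelerations, times) -> PhaseTrajectory:
    """Propagate an initial state through per-interval constant accelerations.

    The closed form used throughout the solvers is

        p_k = p_0 + v_0 (t_k - t_0)
              + sum_{i<k} [T_i^2/2 + T_i (t_k - t_{i+1})] a_i
        v_k = v_0 + sum_{i<k} T_i a_i

    which is the unique trajectory with the given initial state.

    Parameters
    ----------
    p0, v0 : float or array, shape (d,)
        Initial position (m) and velocity (m/s).
    accelerations : array, shape (m-1,) or (m-1, d)
        Constant acceleration per interval (m/s^2).
    times : array, shape (m,)
        Strictly increasing sample times (s).
    """
    times = _as_float_array(times, "times")
    _check_times(times)
    a = _as_float_array(accelerations, "accelerations")
    if a.shape[0] != times.size - 1:
        raise InvalidInputError("need one acceleration per interval")
    p0 = np.asarray(p0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if p0.shape != a.shape[1:] or v0.shape != a.shape[1:]:
        raise InvalidInputError("p0/v0 shape inconsistent with accelerations")
    T = np.diff(times)
    Tc = _col(T, a)
    dv = a * Tc
    v = np.concatenate([v0[None, ...], v0 + np.cumsum(dv, axis=0)], axis=0)
    dp = v[:-1] * Tc + 0.5 * a * Tc**2
    p = np.concatenate([p0[None, ...], p0 + np.cumsum(dp, axis=0)], axis=0)
    return PhaseTrajectory(times, p, v, a)


def rms_error(estimate, reference) -> float:
    """Root-mean-square error between two coordinate series.

    ``E = sqrt( (1/S) sum_i sum_dims (ref_i - est_i)^2 )`` with the inner sum
    over however many coordinates are present.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise InvalidInputError(
            f"shape mismatch: {est.shape} vs {ref.shape}")
    if est.shape[0] < 1:
        raise InvalidInputError("need at least one sample")
    diff2 = (ref - est) ** 2
    if diff2.ndim > 1:
        diff2 = diff2.sum(axis=tuple(range(1, diff2.ndim)))
    return float(np.sqrt(diff2.mean()))
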