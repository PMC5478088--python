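"""Newtonian-constrained least-squares smoothing (the shadowing filter).

Given noisy position fixes ``P_i`` at times ``t_i`` with error variances
``sigma_i^2``, the filter finds the Newton-consistent trajectory
``(p, v, a)`` minimizing

    J = 1/2 * sum_i sigma_i^-2 (P_i - p_i)^2  +  eta * sum_i T_i a_i^2

subject to the piecewise-constant-acceleration constraints

    p_{i+1} = p_i + v_i T_i + a_i T_i^2 / 2,    v_{i+1} = v_i + a_i T_i.

The smoothing weight ``eta`` trades observation fidelity against
acceleration energy: ``eta -> 0`` interpolates the fixes, ``eta -> inf``
forces the weighted-least-squares straight line.  High-dimensional tracks
are filtered as independent scalar problems per coordinate.

Two solvers are provided and agree to solver precision:

``reduced`` (default)
    Eliminates the constraints by parameterizing trajectories with
    ``u = (p_0, v_0, a_0, ..., a_{n-1})`` via the closed-form propagation of
    :func:`~shadowtrack.tracks.newton_propagate`, and solves the resulting
    linear least-squares problem by SVD with the minimum-norm convention.
    Residual rows are weighted by ``1/sigma_i`` and acceleration-penalty
    rows by ``sqrt(2 eta T_i)`` so the squared system equals ``2 J``.

``kkt``
    Solves the full first-order stationarity system of the Lagrangian in
    all unknowns ``(p, v, a, lambda, mu)``, returning the Lagrange
    multipliers as diagnostics.  Serves as an independent verification
    route for the reduced solver.

The hard acceleration bound ``sum_i T_i a_i^2 <= (t_n - t_0) xi^2`` that
motivates the penalty is never enforced: its left-hand side is controlled
through ``eta`` directly, and the bound's constant drops out of every
stationarity derivative.  ``FilterConfig.xi_bound`` records the value for
documentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .exceptions import DegenerateProblemError, InvalidInputError
from .tracks import ObservationSeries, PhaseTrajectory, newton_propagate

__all__ = [
    "FilterConfig",
    "ConditionReport",
    "KKTDiagnostics",
    "ShadowingFilter",
    "shadow_filter",
    "kkt_solve",
    "filter_track",
    "objective_value",
]

_SOLVERS = ("reduced", "kkt")


@dataclass(frozen=True)
class FilterConfig:
    """Filter settings.

    Parameters
    ----------
    eta : float
        Dimensionless smoothing weight, >= 0.
    solver : {"reduced", "kkt"}
        Constraint-eliminated SVD least squares (default) or the full
        stationarity system with multipliers.
    svd_rcond : float
        Relative singular-value truncation threshold, in (0, 1).
    xi_bound : float, optional
        Documentation-only record of the acceleration bound xi (m/s^2);
        never enforced.
    """

    eta: float = 0.05
    solver: str = "reduced"
    svd_rcond: float = 1e-12
    xi_bound: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.eta) or self.eta < 0:
            raise InvalidInputError("eta must be finite and >= 0")
        if self.solver not in _SOLVERS:
            raise InvalidInputError(f"solver must be one of {_SOLVERS}")
        if not (0.0 < self.svd_rcond < 1.0):
            raise InvalidInputError("svd_rcond must lie in (0, 1)")


@dataclass(frozen=True)
class ConditionReport:
    """Rank/conditioning report of one scalar solve."""

    rank: int
    n_unknowns: int
    singular_value_max: float
    singular_value_min: float

    @property
    def underdetermined(self) -> bool:
        return self.rank < self.n_unknowns


@dataclass(frozen=True)
class KKTDiagnostics:
    """Lagrange multipliers and stationarity residual of one KKT solve.

    ``lambda_multipliers[i]`` and ``mu_multipliers[i]`` are the multipliers
    of the position and velocity constraints closing interval ``i``
    (indices 1..n in the usual notation).
    """

    lambda_multipliers: np.ndarray
    mu_multipliers: np.ndarray
    stationarity_residual_max: float


def _reduced_design(times: np.ndarray) -> np.ndarray:
    """Map u = (p0, v0, a_0..a_{n-1}) to sample positions.

    Column for a_i at sample k (k > i): T_i^2/2 + T_i (t_k - t_{i+1}).
    """
    m = times.size
    n = m - 1
    T = np.diff(times)
    A = np.zeros((m, n + 2))
    A[:, 0] = 1.0
    A[:, 1] = times - times[0]
    if n:
        C = 0.5 * T[None, :] ** 2 + T[None, :] * (times[:, None] - times[1:][None, :])
        mask = np.arange(m)[:, None] > np.arange(n)[None, :]
        A[:, 2:] = np.where(mask, C, 0.0)
    return A


def _solve_reduced(times, P, variances, eta, rcond):
    m = times.size
    n = m - 1
    T = np.diff(times)
    w = 1.0 / np.sqrt(variances)
    M = np.zeros((m + n, n + 2))
    M[:m] = _reduced_design(times) * w[:, None]
    if n:
        M[m:, 2:] = np.diag(np.sqrt(2.0 * eta * T))
    rhs = np.concatenate([w * P, np.zeros(n)])
    sol, _, rank, sv = scipy.linalg.lstsq(M, rhs, cond=rcond,
                                          lapack_driver="gelsd")
    report = ConditionReport(rank=int(rank), n_unknowns=n + 2,
                             singular_value_max=float(sv[0]),
                             singular_value_min=float(sv[-1]))
    return float(sol[0]), float(sol[1]), sol[2:], report


def _solve_kkt(times, P, variances, eta, rcond):
    """Assemble and solve the stationarity system.

    Unknown ordering: p_0..p_n, v_0..v_n, a_0..a_{n-1}, lam_1..lam_n,
    mu_1..mu_n.  The equations (derived from the objective-plus-constraints
    Lagrangian and verified against finite-difference gradients in the test
    suite) are, with lam_0 = lam_{n+1} = mu_0 = mu_{n+1} = 0:

        dL/dp_i:  p_i / s_i^2 + lam_i - lam_{i+1} = P_i / s_i^2
        dL/dv_i:  mu_i - mu_{i+1} - T_i lam_{i+1} = 0
        dL/da_i:  2 eta T_i a_i - T_i^2/2 lam_{i+1} - T_i mu_{i+1} = 0
        constraints: the two Newtonian recursions.
    """
    m = times.size
    n = m - 1
    T = np.diff(times)
    size = 5 * n + 2
    ip = lambda i: i
    iv = lambda i: (n + 1) + i
    ia = lambda i: 2 * (n + 1) + i
    il = lambda i: 2 * (n + 1) + n + i      # lam_{i+1}, i = 0..n-1
    im = lambda i: 2 * (n + 1) + 2 * n + i  # mu_{i+1}
    M = np.zeros((size, size))
    b = np.zeros(size)
    row = 0
    for i in range(m):  # dL/dp_i
        M[row, ip(i)] = 1.0 / variances[i]
        if i >= 1:
            M[row, il(i - 1)] += 1.0
        if i <= n - 1:
            M[row, il(i)] -= 1.0
        b[row] = P[i] / variances[i]
        row += 1
    for i in range(m):  # dL/dv_i
        if i <= n - 1:
            M[row, il(i)] -= T[i]
        if i >= 1:
            M[row, im(i - 1)] += 1.0
        if i <= n - 1:
            M[row, im(i)] -= 1.0
        row += 1
    for i in range(n):  # dL/da_i
        M[row, ia(i)] = 2.0 * eta * T[i]
        M[row, il(i)] = -0.5 * T[i] ** 2
        M[row, im(i)] = -T[i]
        row += 1
    for i in range(n):  # position constraint closing interval i
        M[row, ip(i + 1)] = 1.0
        M[row, ip(i)] = -1.0
        M[row, iv(i)] = -T[i]
        M[row, ia(i)] = -0.5 * T[i] ** 2
        row += 1
    for i in range(n):  # velocity constraint
        M[row, iv(i + 1)] = 1.0
        M[row, iv(i)] = -1.0
        M[row, ia(i)] = -T[i]
        row += 1
    z, _, rank, _ = scipy.linalg.lstsq(M, b, cond=rcond, lapack_driver="gelsd")
    if rank < size:
        raise DegenerateProblemError(
            f"stationarity system rank deficient ({rank} < {size})",
            rank_deficit=size - rank)
    residual = float(np.max(np.abs(M @ z - b))) if size else 0.0
    a = z[ia(0):ia(0) + n]
    lam = z[il(0):il(0) + n]
    mu = z[im(0):im(0) + n]
    diag = KKTDiagnostics(lambda_multipliers=lam, mu_multipliers=mu,
                          stationarity_residual_max=residual)
    return float(z[ip(0)]), float(z[iv(0)]), a, diag


class ShadowingFilter(BaseEstimator):
    """Batch shadowing filter as a scikit-learn style estimator.

    ``fit`` takes the noisy positions (one column per coordinate) and
    reconstructs the closest Newtonian trajectory; the full phase space is
    then available as fitted attributes.  The filter is a whole-series
    batch smoother, so there is no out-of-sample ``transform``:
    ``fit_transform(X, ...)`` returns the smoothed positions for the
    fitted series.

    Parameters
    ----------
    eta : float, default 0.05
        Smoothing weight (>= 0).  0.05 is the value appropriate for GPS
        fixes with ~0.4 m^2 error variance at high sampling rate; see
        :func:`shadowtrack.eta_selection.eta_from_noise`.
    solver : {"reduced", "kkt"}, default "reduced"
    svd_rcond : float, default 1e-12
        Relative SVD truncation threshold.
    xi_bound : float, optional
        Documentation-only acceleration bound; never enforced.

    Attributes
    ----------
    trajectory_ : PhaseTrajectory
    positions_, velocities_ : ndarray, shape like X
    accelerations_ : ndarray, one row per interval
    condition_reports_ : list of ConditionReport, one per coordinate
    diagnostics_ : list of KKTDiagnostics (kkt solver only)
    n_features_in_ : int

    Examples
    --------
    >>> import numpy as np
    >>> t = np.arange(5, dtype=float)
    >>> est = ShadowingFilter(eta=0.05).fit(3 + 2 * t, times=t)
    >>> np.allclose(est.velocities_, 2.0)
    True
    """

    def __init__(self, eta: float = 0.05, solver: str = "reduced",
                 svd_rcond: float = 1e-12, xi_bound: Optional[float] = None):
        self.eta = eta
        self.solver = solver
        self.svd_rcond = svd_rcond
        self.xi_bound = xi_bound

    def _config(self) -> FilterConfig:
        return FilterConfig(eta=self.eta, solver=self.solver,
                            svd_rcond=self.svd_rcond, xi_bound=self.xi_bound)

    def fit(self, X, y=None, *, times=None, error_variances=None,
            valid_flags=None):
        """Reconstruct the trajectory closest to the observations.

        Parameters
        ----------
        X : array, shape (m,) or (m, d)
            Noisy positions in meters.
        times : array, shape (m,), optional
            Sample times in seconds; defaults to 0, 1, ..., m-1.
        error_variances : array, shape (m,), optional
            Per-sample error variances (default 1).
        valid_flags : bool array, shape (m,), optional
            Stored on ``observations_``; flagged samples are *not* dropped
            here — drop them before fitting if desired.
        """
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        if times is None:
            times = np.arange(X.shape[0], dtype=float)
        obs = ObservationSeries(times, X, error_variances, valid_flags)
        if obs.n_samples < 2:
            raise InvalidInputError("need at least 2 samples to filter")
        d = obs.n_dims
        scalar = obs.values.ndim == 1
        cols = [obs.values] if scalar else [obs.values[:, k] for k in range(d)]
        p0 = np.empty(d)
        v0 = np.empty(d)
        a = np.empty((obs.n_samples - 1, d))
        reports, diags = [], []
        for k, col in enumerate(cols):
            if cfg.solver == "kkt":
                if cfg.eta <= 0:
                    raise InvalidInputError("kkt solver requires eta > 0")
                p0[k], v0[k], a[:, k], diag = _solve_kkt(
                    obs.times, col, obs.error_variances, cfg.eta,
                    cfg.svd_rcond)
                diags.append(diag)
            else:
                p0[k], v0[k], a[:, k], report = _solve_reduced(
                    obs.times, col, obs.error_variances, cfg.eta,
                    cfg.svd_rcond)
                reports.append(report)
        if scalar:
            traj = newton_propagate(p0[0], v0[0], a[:, 0], obs.times)
        else:
            traj = newton_propagate(p0, v0, a, obs.times)
        self.observations_ = obs
        self.trajectory_ = traj
        self.positions_ = traj.positions
        self.velocities_ = traj.velocities
        self.accelerations_ = traj.accelerations
        self.condition_reports_ = reports
        self.diagnostics_ = diags
        self.n_features_in_ = d
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit the filter and return the smoothed positions."""
        return self.fit(X, y, **fit_params).positions_

    def transform(self, X=None) -> np.ndarray:
        """Return the smoothed positions of the fitted series.

        A batch smoother has no out-of-sample mapping, so ``X`` is ignored
        and may be None.
        """
        if not hasattr(self, "trajectory_"):
            raise NotFittedError("ShadowingFilter is not fitted yet")
        return self.positions_


def shadow_filter(obs: ObservationSeries, config: FilterConfig = None, *,
                  return_report: bool = False):
    """Filter one scalar coordinate series; thin functional wrapper over
    :class:`ShadowingFilter`.

    Returns the :class:`PhaseTrajectory`, or ``(trajectory, report)`` with
    the rank/conditioning report when ``return_report`` is true.
    """
    if obs.values.ndim != 1:
        raise InvalidInputError(
            "shadow_filter takes one coordinate; use filter_track for d >= 2")
    config = config or FilterConfig()
    est = ShadowingFilter(**_params(config)).fit(
        obs.values, times=obs.times, error_variances=obs.error_variances,
        valid_flags=obs.valid_flags)
    if return_report:
        rep = est.condition_reports_[0] if est.condition_reports_ else None
        return est.trajectory_, rep
    return est.trajectory_


def kkt_solve(obs: ObservationSeries, config: FilterConfig = None):
    """Solve the full stationarity system for one scalar coordinate.

    Returns ``(trajectory, diagnostics)`` where the diagnostics carry the
    Lagrange multipliers; requires ``eta > 0``.
    """
    if obs.values.ndim != 1:
        raise InvalidInputError("kkt_solve takes one coordinate")
    config = config or FilterConfig()
    params = _params(config)
    params["solver"] = "kkt"
    est = ShadowingFilter(**params).fit(
        obs.values, times=obs.times, error_variances=obs.error_variances,
        valid_flags=obs.valid_flags)
    return est.trajectory_, est.diagnostics_[0]


def filter_track(obs: ObservationSeries, config: FilterConfig = None,
                 *, return_reports: bool = False):
    """Filter a d-coordinate track by independent scalar application."""
    config = config or FilterConfig()
    est = ShadowingFilter(**_params(config)).fit(
        obs.values, times=obs.times, error_variances=obs.error_variances,
        valid_flags=obs.valid_flags)
    if return_reports:
        return est.trajectory_, est.condition_reports_
    return est.trajectory_


def _params(config: FilterConfig) -> dict:
    return {"eta": config.eta, "solver": config.solver,
            "svd_rcond": config.svd_rcond, "xi_bound": config.xi_bound}


def objective_value(obs: ObservationSeries, traj: PhaseTrajectory,
                    eta: float):
    """Evaluate the smoothing objective at a trajectory.

    Returns ``(total, misfit, penalty)`` with
    ``misfit = 1/2 sum_i sigma_i^-2 (P_i - p_i)^2``,
    ``penalty = sum_i T_i a_i^2`` and ``total = misfit + eta * penalty``.
    Multi-coordinate inputs sum over coordinates.
    """
    if traj.n_samples != obs.n_samples or traj.positions.shape != obs.values.shape:
        raise InvalidInputError("observation and trajectory shapes differ")
    r2 = (obs.values - traj.positions) ** 2
    if r2.ndim > 1:
        r2 = r2.sum(axis=1)
    misfit = 0.5 * float(np.sum(r2 / obs.error_variances))
    T = np.diff(obs.times)
    a2 = traj.accelerations ** 2
    if a2.ndim > 1:
        a2 = a2.sum(axis=1)
    penalty = float(np.sum(T * a2))
    return misfit + eta * penalty, misfit, penalty
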