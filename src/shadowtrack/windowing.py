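"""Windowing test: minimum observation length for reliable tracking.

The filter is applied to suffix sub-series of increasing length n (always
anchored at the most recent sample).  For each n, the per-sample distances

    D_{j,n} = || P_{N-j} - q_{N-j} ||,   0 <= j < n,

between the observations and the length-n reconstruction are recorded,
together with the reconstructed last state.  Convergence of the last state
toward the full-window estimate as n grows gives the minimum window length
required; consistency of that convergence is a practical reliability check
of both the filter and the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core_filter import FilterConfig, filter_track
from .exceptions import InvalidInputError
from .tracks import ObservationSeries

__all__ = ["WindowingResult", "windowing_test", "min_window_length"]


def default_tolerance(noise_std: Optional[float] = None) -> float:
    """Convergence tolerance for the last state: max(0.05 m, noise_std/10)."""
    tol = 0.05
    if noise_std is not None:
        tol = max(tol, float(noise_std) / 10.0)
    return tol


@dataclass(frozen=True)
class WindowingResult:
    """Distance curves per window length and the inferred minimum length.

    ``distances[k][j]`` is D_{j, n_k}: the residual at the sample j steps
    before the end, for window length ``window_lengths[k]``.
    ``last_state_estimates[k]`` is the reconstructed final position q_N.
    ``min_window_length`` is None when convergence was not reached at the
    stored tolerance.
    """

    window_lengths: List[int]
    distances: List[np.ndarray]
    last_state_estimates: np.ndarray
    full_length: int
    tol: float
    min_window_length: Optional[int]
    skipped: List[int] = None


def windowing_test(obs: ObservationSeries, eta: float,
                   window_lengths: Sequence[int],
                   tol: Optional[float] = None,
                   noise_std: Optional[float] = None,
                   base_config: FilterConfig = None) -> WindowingResult:
    """Filter suffixes of increasing length at fixed eta.

    The full window (all N samples) is always included as the convergence
    reference.  Window lengths below 2 are skipped with a warning.
    """
    if eta <= 0:
        raise InvalidInputError("windowing test requires eta > 0")
    base = base_config or FilterConfig()
    cfg = FilterConfig(eta=float(eta), solver=base.solver,
                       svd_rcond=base.svd_rcond, xi_bound=base.xi_bound)
    N = obs.n_samples
    requested = sorted(set(int(n) for n in window_lengths) | {N})
    skipped = [n for n in requested if n < 2]
    if skipped:
        warnings.warn(f"window lengths {skipped} below 2 were skipped")
    lengths = [n for n in requested if 2 <= n <= N]
    bad = [n for n in requested if n > N]
    if bad:
        raise InvalidInputError(f"window lengths {bad} exceed series length {N}")
    distances = []
    last_states = []
    for n in lengths:
        sub = obs.take(np.arange(N - n, N))
        traj = filter_track(sub, cfg)
        resid = sub.values - traj.positions
        if resid.ndim > 1:
            d = np.sqrt(np.sum(resid**2, axis=1))
        else:
            d = np.abs(resid)
        distances.append(d[::-1])  # j = 0 is the most recent sample
        last_states.append(np.atleast_1d(traj.positions[-1]))
    last_states = np.asarray(last_states)
    tol = default_tolerance(noise_std) if tol is None else float(tol)
    result = WindowingResult(window_lengths=lengths, distances=distances,
                             last_state_estimates=last_states,
                             full_length=N, tol=tol, min_window_length=None,
                             skipped=skipped)
    n_min = min_window_length(result, tol)
    return WindowingResult(window_lengths=lengths, distances=distances,
                           last_state_estimates=last_states,
                           full_length=N, tol=tol, min_window_length=n_min,
                           skipped=skipped)


def min_window_length(result: WindowingResult, tol: float) -> Optional[int]:
    """Smallest tested n whose whole tail has converged at the last state.

    Returns the smallest tested n such that
    ``|| q_N(n') - q_N(full) || <= tol`` for *all* tested n' >= n (a uniform
    tail condition, not the first crossing).  The full window is the
    reference, not a candidate: when no shorter window satisfies the
    condition, convergence was not reached and None is returned.
    """
    lengths = result.window_lengths
    if result.full_length not in lengths:
        raise InvalidInputError("result lacks the full-window reference row")
    ref = result.last_state_estimates[lengths.index(result.full_length)]
    dev = np.sqrt(np.sum(
        (result.last_state_estimates - ref[None, :]) ** 2, axis=1))
    ok = dev <= tol
    # uniform over the tail: converged from index k onward
    tail_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = [i for i in np.flatnonzero(tail_ok)
            if lengths[i] < result.full_length]
    if not hits:
        return None
    return int(lengths[hits[0]])
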