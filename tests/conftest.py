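import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

from shadowtrack import ObservationSeries


@pytest.fixture
def random_scalar_obs():
    """Factory for small random irregular scalar observation series."""

    def make(seed: int, m: int = 8, with_variances: bool = True):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.1, 1.0, m))
        P = rng.normal(0.0, 5.0, m)
        var = rng.uniform(0.5, 2.0, m) if with_variances else None
        return ObservationSeries(t, P, error_variances=var)

    return make


def constrained_qp_oracle(obs, eta):
    """Generic dense equality-constrained QP solve of the smoothing problem.

    Minimizes 1/2 z^T H z - q^T z over z = (p_0..p_n, v_0..v_n,
    a_0..a_{n-1}) subject to the Newtonian equality constraints A z = 0,
    via the saddle-point (block KKT) linear system.  Independent of the
    package's solvers: no constraint elimination, no hand-derived
    stationarity recursions.

    Returns (p, v, a, objective_value).
    """
    t = obs.times
    P = obs.values
    var = obs.error_variances
    m = t.size
    n = m - 1
    T = np.diff(t)
    nz = 3 * m - 1  # p, v, a
    H = np.zeros((nz, nz))
    q = np.zeros(nz)
    H[:m, :m] = np.diag(1.0 / var)
    q[:m] = P / var
    H[2 * m:, 2 * m:] = np.diag(2.0 * eta * T)
    A = np.zeros((2 * n, nz))
    for i in range(n):
        A[i, i + 1] = 1.0
        A[i, i] = -1.0
        A[i, m + i] = -T[i]
        A[i, 2 * m + i] = -0.5 * T[i] ** 2
        A[n + i, m + i + 1] = 1.0
        A[n + i, m + i] = -1.0
        A[n + i, 2 * m + i] = -T[i]
    KKT = np.block([[H, A.T], [A, np.zeros((2 * n, 2 * n))]])
    rhs = np.concatenate([q, np.zeros(2 * n)])
    sol = np.linalg.solve(KKT, rhs)
    z = sol[:nz]
    p, v, a = z[:m], z[m:2 * m], z[2 * m:]
    obj = 0.5 * np.sum((P - p) ** 2 / var) + eta * np.sum(T * a**2)
    return p, v, a, obj
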