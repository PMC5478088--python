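"""Shadowing-filter solvers: correctness against independent oracles and
the structural invariants of the constrained quadratic problem."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from shadowtrack import (FilterConfig, InvalidInputError, ObservationSeries,
                         ShadowingFilter, filter_track, kkt_solve,
                         newton_propagate, objective_value, shadow_filter)
from shadowtrack.core_filter import _reduced_design

from conftest import constrained_qp_oracle


def _rel(a, b):
    scale = max(np.abs(b).max(), 1.0)
    return np.abs(np.asarray(a) - np.asarray(b)).max() / scale


class TestExactFits:
    def test_affine_data_fits_exactly(self):
        # unpenalized affine motion: objective 0 attainable at any eta
        t = np.linspace(0.0, 5.0, 9)
        P = 3.0 + 2.0 * t
        obs = ObservationSeries(t, P, error_variances=np.full(9, 0.7))
        traj = shadow_filter(obs, FilterConfig(eta=0.05))
        np.testing.assert_allclose(traj.positions, P, atol=1e-9)
        np.testing.assert_allclose(traj.velocities, 2.0, atol=1e-9)
        np.testing.assert_allclose(traj.accelerations, 0.0, atol=1e-9)

    def test_noiseless_track_recovered_at_small_eta(self):
        # Constant acceleration over an even number of intervals has no
        # component along the filter's invisible alternating mode, so the
        # eta -> 0 limit recovers the full phase space, not just positions.
        t = np.arange(31) * 0.2
        truth = newton_propagate(1.0, -2.0, np.full(30, 3.0), t)
        obs = ObservationSeries(t, truth.positions)
        traj = shadow_filter(obs, FilterConfig(eta=1e-12))
        assert _rel(traj.positions, truth.positions) < 1e-6
        assert np.abs(traj.velocities - truth.velocities).max() < 1e-6
        assert np.abs(traj.accelerations - truth.accelerations).max() < 1e-6

    def test_positions_interpolated_in_zero_noise_limit(self):
        # generic rough truth: positions are recovered even though v, a
        # retain the invisible-mode ambiguity
        rng = np.random.default_rng(7)
        t = np.arange(40) * 0.2
        truth = newton_propagate(0.0, 0.0, rng.uniform(-4, 4, 39), t)
        obs = ObservationSeries(t, truth.positions)
        traj = shadow_filter(obs, FilterConfig(eta=1e-12))
        assert np.abs(traj.positions - truth.positions).max() < 1e-6


class TestOracleEquivalence:
    def test_objective_matches_dense_qp(self, random_scalar_obs):
        obs = random_scalar_obs(seed=42, m=6)
        eta = 0.1
        traj = shadow_filter(obs, FilterConfig(eta=eta))
        total, _, _ = objective_value(obs, traj, eta)
        _, _, _, obj_oracle = constrained_qp_oracle(obs, eta)
        assert abs(total - obj_oracle) <= 1e-8 * max(1.0, abs(obj_oracle))

    @pytest.mark.parametrize("seed", range(10))
    def test_three_routes_agree(self, seed, random_scalar_obs):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 20))
        obs = random_scalar_obs(seed=seed, m=m)
        eta = float(10.0 ** rng.uniform(-3, 0))
        t_red = shadow_filter(obs, FilterConfig(eta=eta))
        t_kkt, _ = kkt_solve(obs, FilterConfig(eta=eta))
        p_qp, v_qp, a_qp, _ = constrained_qp_oracle(obs, eta)
        assert _rel(t_red.positions, p_qp) < 1e-8
        assert _rel(t_kkt.positions, p_qp) < 1e-8
        assert _rel(t_red.velocities, v_qp) < 1e-8
        assert _rel(t_red.accelerations, a_qp) < 1e-8


class TestKKTSolver:
    def test_projected_gradient_vanishes(self, random_scalar_obs):
        # finite-difference gradient of J in the constraint-manifold chart
        # u = (p0, v0, a) is zero at the returned minimizer
        obs = random_scalar_obs(seed=3, m=7)
        eta = 0.2
        traj, diag = kkt_solve(obs, FilterConfig(eta=eta))
        T = np.diff(obs.times)

        def J(u):
            tr = newton_propagate(u[0], u[1], u[2:], obs.times)
            return (0.5 * np.sum((obs.values - tr.positions) ** 2
                                 / obs.error_variances)
                    + eta * np.sum(T * tr.accelerations**2))

        u0 = np.concatenate([[traj.positions[0], traj.velocities[0]],
                             traj.accelerations])
        h = 1e-6
        grad = np.array([
            (J(u0 + h * e) - J(u0 - h * e)) / (2 * h)
            for e in np.eye(u0.size)
        ])
        assert np.abs(grad).max() < 1e-6 * max(1.0, abs(J(u0)))
        assert diag.stationarity_residual_max < 1e-8

    def test_exact_line_gives_zero_multipliers(self):
        t = np.linspace(0.0, 4.0, 6)
        obs = ObservationSeries(t, 1.0 - 3.0 * t)
        _, diag = kkt_solve(obs, FilterConfig(eta=0.5))
        assert np.abs(diag.lambda_multipliers).max() < 1e-9
        assert np.abs(diag.mu_multipliers).max() < 1e-9

    def test_requires_positive_eta(self, random_scalar_obs):
        with pytest.raises(InvalidInputError):
            kkt_solve(random_scalar_obs(seed=0), FilterConfig(eta=0.0))


class TestStructuralInvariants:
    def test_straight_line_limit_is_weighted_regression(self,
                                                        random_scalar_obs):
        obs = random_scalar_obs(seed=11, m=12)
        traj = shadow_filter(obs, FilterConfig(eta=1e12))
        w = 1.0 / obs.error_variances
        X = np.column_stack([np.ones_like(obs.times), obs.times])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * obs.values))
        assert np.abs(traj.positions - X @ coef).max() < 1e-6
        assert np.abs(traj.accelerations).max() < 1e-6

    def test_misfit_penalty_monotone_in_eta(self, random_scalar_obs):
        obs = random_scalar_obs(seed=5, m=15)
        misfits, penalties = [], []
        for eta in np.geomspace(1e-4, 10, 12):
            traj = shadow_filter(obs, FilterConfig(eta=eta))
            _, misfit, penalty = objective_value(obs, traj, eta)
            misfits.append(misfit)
            penalties.append(penalty)
        assert np.all(np.diff(misfits) >= -1e-10)
        assert np.all(np.diff(penalties) <= 1e-10)

    @given(alpha=hst.floats(-100, 100), beta=hst.floats(-20, 20))
    def test_galilean_invariance(self, alpha, beta):
        rng = np.random.default_rng(17)
        t = np.cumsum(rng.uniform(0.1, 0.5, 10))
        P = rng.normal(0, 3, 10)
        obs = ObservationSeries(t, P)
        shifted = ObservationSeries(t, P + alpha + beta * t)
        base = shadow_filter(obs, FilterConfig(eta=0.3))
        moved = shadow_filter(shifted, FilterConfig(eta=0.3))
        scale = max(1.0, np.abs(moved.positions).max())
        assert np.abs(moved.positions - (base.positions + alpha + beta * t)
                      ).max() < 1e-8 * scale
        assert np.abs(moved.velocities - (base.velocities + beta)
                      ).max() < 1e-8 * scale
        assert np.abs(moved.accelerations - base.accelerations
                      ).max() < 1e-8 * scale

    def test_sigma_eta_rescaling_equivalence(self, random_scalar_obs):
        # scaling all variances by c is the same problem as scaling eta by c
        obs = random_scalar_obs(seed=23, m=9)
        c = 3.7
        scaled = ObservationSeries(obs.times, obs.values,
                                   error_variances=c * obs.error_variances)
        a = shadow_filter(scaled, FilterConfig(eta=0.08))
        b = shadow_filter(obs, FilterConfig(eta=0.08 * c))
        assert _rel(a.positions, b.positions) < 1e-8

    def test_dropout_equals_never_present(self):
        # filtering after removing flagged samples is identical to a series
        # that never contained them
        rng = np.random.default_rng(2)
        t = np.arange(20) * 0.2
        P = rng.normal(0, 2, 20)
        flags = np.ones(20, dtype=bool)
        flags[[3, 7, 8, 15]] = False
        full = ObservationSeries(t, P, valid_flags=flags)
        never = ObservationSeries(t[flags], P[flags])
        a = shadow_filter(full.drop_invalid(), FilterConfig(eta=0.05))
        b = shadow_filter(never, FilterConfig(eta=0.05))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.accelerations, b.accelerations)


class TestMultiDimensional:
    def test_columns_match_scalar_calls_bitwise(self):
        rng = np.random.default_rng(9)
        t = np.arange(12) * 0.5
        V = rng.normal(0, 4, (12, 3))
        obs = ObservationSeries(t, V)
        traj = filter_track(obs, FilterConfig(eta=0.1))
        for k in range(3):
            scalar = shadow_filter(obs.coordinate(k), FilterConfig(eta=0.1))
            np.testing.assert_array_equal(traj.positions[:, k],
                                          scalar.positions)
            np.testing.assert_array_equal(traj.accelerations[:, k],
                                          scalar.accelerations)

    def test_coordinate_permutation(self):
        rng = np.random.default_rng(10)
        t = np.arange(10, dtype=float)
        V = rng.normal(0, 4, (10, 3))
        perm = [2, 0, 1]
        a = filter_track(ObservationSeries(t, V), FilterConfig(eta=0.1))
        b = filter_track(ObservationSeries(t, V[:, perm]),
                         FilterConfig(eta=0.1))
        np.testing.assert_array_equal(a.positions[:, perm], b.positions)

    def test_shadow_filter_rejects_multidim(self):
        obs = ObservationSeries([0.0, 1.0], np.zeros((2, 2)))
        with pytest.raises(InvalidInputError):
            shadow_filter(obs)


class TestDegenerateAndErrors:
    def test_eta_zero_minimum_norm_with_report(self, random_scalar_obs):
        obs = random_scalar_obs(seed=1, m=5)
        traj, report = shadow_filter(obs, FilterConfig(eta=0.0),
                                     return_report=True)
        assert report.underdetermined
        assert report.rank == obs.n_samples  # m position rows, m+1 unknowns
        np.testing.assert_allclose(traj.positions, obs.values, atol=1e-8)

    def test_too_few_samples(self):
        obs = ObservationSeries([0.0], [1.0])
        with pytest.raises(InvalidInputError):
            shadow_filter(obs)

    def test_objective_value_cases(self):
        t = np.array([0.0, 1.0])
        obs = ObservationSeries(t, np.array([1.0, 0.0]))
        traj = newton_propagate(0.0, -1.0, [2.0], t)  # p = (0, 0), resid (1,0)
        total, misfit, penalty = objective_value(obs, traj, eta=0.5)
        assert misfit == pytest.approx(0.5)
        assert penalty == pytest.approx(4.0)
        assert total == pytest.approx(2.5)
        exact = shadow_filter(obs, FilterConfig(eta=1e-9))
        tot0, mis0, pen0 = objective_value(
            obs, newton_propagate(exact.positions[0], exact.velocities[0],
                                  exact.accelerations, t), 0.0)
        assert mis0 < 1e-12

    def test_objective_length_mismatch(self):
        obs = ObservationSeries([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        traj = newton_propagate(0.0, 1.0, [0.0], [0.0, 1.0])
        with pytest.raises(InvalidInputError):
            objective_value(obs, traj, 0.1)


class TestEstimatorAPI:
    def test_params_clone_and_fit_transform(self):
        est = ShadowingFilter(eta=0.2, solver="kkt")
        assert clone(est).get_params()["eta"] == 0.2
        t = np.arange(8, dtype=float)
        smoothed = est.fit_transform(2.0 * t + 1.0, times=t)
        np.testing.assert_allclose(smoothed, 2.0 * t + 1.0, atol=1e-8)
        assert est.n_features_in_ == 1
        assert len(est.diagnostics_) == 1

    def test_not_fitted(self):
        with pytest.raises(NotFittedError):
            ShadowingFilter().transform()

    def test_default_time_grid(self):
        est = ShadowingFilter(eta=0.1).fit(np.zeros(5))
        np.testing.assert_array_equal(est.trajectory_.times,
                                      np.arange(5.0))

    def test_design_matrix_closed_form(self):
        # column of a_i at sample k is T_i^2/2 + T_i (t_k - t_{i+1})
        t = np.array([0.0, 1.0, 3.0])
        A = _reduced_design(t)
        np.testing.assert_allclose(A[:, 0], 1.0)
        np.testing.assert_allclose(A[:, 1], t)
        np.testing.assert_allclose(A[2, 2], 0.5 + 2.0)  # a_0 at t=3
        np.testing.assert_allclose(A[2, 3], 2.0)        # a_1 at t=3
        assert A[1, 3] == 0.0
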