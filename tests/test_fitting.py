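"""Online Kalman sphere fitting and direct constrained ellipsoid fitting."""

import time

import numpy as np
import pytest

from eyefit.fitting import (
    ImmatureStateError,
    KalmanState,
    batch_sphere_fit,
    ef_fit,
    sf_update,
    sphere_from_state,
    sphere_kalman_init,
    sphere_rms_residual,
)
from eyefit.geometry import (
    EllipsoidParams,
    evaluate_ellipsoid_constraint,
    surface_distances,
)
from conftest import random_rotation


def sphere_points(center, radius, n, rng, sigma=0.0):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    return u * radius + center + sigma * rng.normal(size=(n, 3))


class TestKalmanSphereFit:
    def test_noiseless_points_recover_sphere(self, rng):
        pts = sphere_points([1.0, -2.0, 3.0], 11.0, 40, rng)
        state = sphere_kalman_init(prior_variance=1e8)
        for p in pts:
            state = sf_update(state, p)
        s = sphere_from_state(state)
        np.testing.assert_allclose(s.center, [1, -2, 3], atol=1e-6)
        assert s.radius == pytest.approx(11.0, abs=1e-6)

    def test_matches_batch_least_squares(self, rng):
        # zero process noise: the filter is recursive least squares, so its
        # state equals the exact batch posterior (normal equations carrying
        # the same prior) and, with a diffuse prior, plain least squares
        pts = sphere_points([0.5, 1.0, -2.0], 12.0, 60, rng, sigma=0.05)
        prior_var = 1e6
        state = KalmanState(np.zeros(4), prior_var * np.eye(4), 0)
        for p in pts:
            state = sf_update(state, p, measurement_variance=1.0)
        H = np.column_stack([pts, np.ones(len(pts))])
        z = (pts**2).sum(axis=1)
        beta_post = np.linalg.solve(H.T @ H + np.eye(4) / prior_var, H.T @ z)
        np.testing.assert_allclose(state.beta, beta_post, rtol=1e-8, atol=1e-8)
        beta_ls = np.linalg.lstsq(H, z, rcond=None)[0]
        np.testing.assert_allclose(state.beta, beta_ls, rtol=1e-4, atol=1e-4)

    def test_order_independence_in_diffuse_limit(self, rng):
        pts = sphere_points([0, 0, 0], 10.0, 30, rng, sigma=0.02)
        def run(order):
            st = KalmanState(np.zeros(4), 1e6 * np.eye(4), 0)
            for p in pts[order]:
                st = sf_update(st, p, measurement_variance=1.0)
            return st.beta
        np.testing.assert_allclose(
            run(np.arange(30)), run(np.arange(30)[::-1]), rtol=1e-7, atol=1e-7
        )

    def test_covariance_trace_contracts(self, rng):
        state = sphere_kalman_init()
        for p in sphere_points([0, 0, 0], 12.0, 10, rng):
            new = sf_update(state, p)
            assert np.trace(new.covariance) <= np.trace(state.covariance) + 1e-12
            state = new

    def test_nonfinite_point_rejected(self):
        state = sphere_kalman_init()
        assert sf_update(state, [np.nan, 0, 0]) is state

    def test_immature_below_four_points(self, rng):
        state = sphere_kalman_init()
        for p in sphere_points([0, 0, 0], 12.0, 3, rng):
            state = sf_update(state, p)
        with pytest.raises(ImmatureStateError):
            sphere_from_state(state)


class TestSphereFromState:
    def test_origin_state(self):
        s = sphere_from_state(KalmanState([0, 0, 0, 144.0], np.eye(4), 10))
        assert s.radius == pytest.approx(12.0)
        np.testing.assert_allclose(s.center, 0.0)

    def test_closed_form_example(self):
        # beta = (2, -4, 6, 131) -> center (1, -2, 3), r = sqrt(131 + 14)
        s = sphere_from_state(KalmanState([2, -4, 6, 131.0], np.eye(4), 10))
        np.testing.assert_allclose(s.center, [1, -2, 3])
        assert s.radius == pytest.approx(np.sqrt(145.0))

    def test_round_trip_sphere_beta_sphere(self):
        center, r = np.array([2.0, -1.0, 0.5]), 11.5
        beta = np.r_[2 * center, r**2 - center @ center]
        s = sphere_from_state(KalmanState(beta, np.eye(4), 10))
        np.testing.assert_allclose(s.center, center)
        assert s.radius == pytest.approx(r)

    def test_nonphysical_state_errors(self):
        with pytest.raises(ValueError):
            sphere_from_state(KalmanState([0, 0, 0, -1.0], np.eye(4), 10))


class TestEllipsoidFit:
    def test_exact_recovery_noiseless(self, rng):
        semi = np.array([11.0, 12.0, 13.0])
        e = EllipsoidParams(np.sort(semi)[::-1], random_rotation(rng),
                            rng.uniform(-3, 3, 3))
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        res = ef_fit(e.surface_points(u))
        assert res.valid
        np.testing.assert_allclose(res.ellipsoid.semi_axes, e.semi_axes, rtol=1e-6)
        np.testing.assert_allclose(res.ellipsoid.center, e.center, atol=1e-6)
        assert res.rms_residual < 1e-8

    def test_sphere_gives_equal_axes(self, rng):
        pts = sphere_points([1.0, 0.0, -1.0], 12.0, 150, rng)
        res = ef_fit(pts)
        assert res.valid
        np.testing.assert_allclose(res.ellipsoid.semi_axes, 12.0, rtol=1e-6)
        np.testing.assert_allclose(res.ellipsoid.center, [1, 0, -1], atol=1e-6)

    def test_rigid_motion_equivariance(self, rng):
        semi = np.array([13.0, 12.0, 11.0])
        e = EllipsoidParams(semi, np.eye(3), np.zeros(3))
        u = rng.normal(size=(300, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = e.surface_points(u)
        R, t = random_rotation(rng), rng.uniform(-5, 5, 3)
        res = ef_fit(pts @ R.T + t)
        assert res.valid
        np.testing.assert_allclose(res.ellipsoid.semi_axes, semi, rtol=1e-6)
        np.testing.assert_allclose(res.ellipsoid.center, t, atol=1e-6)

    def test_valid_results_satisfy_ellipsoid_constraint(self, rng):
        for _ in range(5):
            pts = sphere_points(rng.uniform(-2, 2, 3), 12.0, 60, rng, sigma=0.02)
            res = ef_fit(pts)
            if res.valid:
                assert evaluate_ellipsoid_constraint(res.quadric) > 0
                assert np.all(np.isfinite(res.ellipsoid.semi_axes))

    def test_shallow_cap_never_silently_hyperboloid(self, rng):
        # < 20 mm lateral extent, 20 um noise: fit may be invalid or poor,
        # but a valid result must satisfy the ellipsoid acceptance test
        theta = rng.uniform(0, 0.7, 300)
        phi = rng.uniform(0, 2 * np.pi, 300)
        pts = 12.0 * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)]
        ) + rng.normal(0, 0.02, (300, 3))
        res = ef_fit(pts)
        if res.valid:
            assert evaluate_ellipsoid_constraint(res.quadric) > 0
        else:
            assert res.ellipsoid is None

    def test_residual_beats_sphere_on_true_ellipsoid(self, rng):
        e = EllipsoidParams(np.array([13.0, 12.0, 10.5]), np.eye(3), np.zeros(3))
        u = rng.normal(size=(500, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = e.surface_points(u) + rng.normal(0, 0.02, (500, 3))
        ef = ef_fit(pts)
        sf = batch_sphere_fit(pts)
        assert ef.valid
        assert ef.rms_residual < sphere_rms_residual(pts, sf.sphere)

    def test_runtime_budget_6000_points(self, rng):
        e = EllipsoidParams(np.array([13.0, 12.0, 11.0]), np.eye(3), np.zeros(3))
        u = rng.normal(size=(6000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = e.surface_points(u) + rng.normal(0, 0.02, (6000, 3))
        ef_fit(pts)  # warm-up
        t0 = time.perf_counter()
        res = ef_fit(pts)
        assert time.perf_counter() - t0 < 0.1
        assert res.valid

    def test_too_few_points_error(self, rng):
        with pytest.raises(ValueError):
            ef_fit(rng.normal(size=(8, 3)))

    def test_geometric_residual_scale(self, rng):
        e = EllipsoidParams(np.array([12.5, 12.0, 11.5]), np.eye(3), np.zeros(3))
        u = rng.normal(size=(2000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = e.surface_points(u) + rng.normal(0, 0.02, (2000, 3))
        res = ef_fit(pts)
        # RMS distance to the fit ~ noise magnitude sqrt(3)*... within a band
        assert 0.01 < res.rms_residual < 0.05
        manual = float(np.sqrt(np.mean(surface_distances(pts, res.ellipsoid) ** 2)))
        assert res.rms_residual == pytest.approx(manual)
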