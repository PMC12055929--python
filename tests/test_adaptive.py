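"""Point reconstruction, transition criteria semantics, adaptive model state."""

import numpy as np
import pytest

import eyefit.adaptive as adaptive
from eyefit.adaptive import (
    AdaptiveEyeModel,
    RetinalPointBuffer,
    TransitionConfig,
    reconstruct_point,
)
from eyefit.fitting import EllipsoidFitResult, ef_fit
from eyefit.geometry import EllipsoidParams, QuadricCoefficients, RigidPose
from conftest import random_rotation


class TestReconstructPoint:
    def test_axial_example(self):
        pose = RigidPose(np.eye(3), np.zeros(3))
        p = reconstruct_point(pose, [0, 0, -1.0], 12.0)
        np.testing.assert_allclose(p, [0, 0, -12.0])

    def test_round_trip_with_simulator(self):
        from eyefit.shapes import build_shape, default_specs
        from eyefit.simulate import SimNoise, SpiralConfig, simulate_scan, spiral_trajectory

        surf = build_shape(default_specs()["emmetropic"])
        traj = spiral_trajectory(SpiralConfig(theta_max=4 * np.pi))
        scan = simulate_scan(traj, surf, surf.anterior_pole, SimNoise(0.0, 0))
        for i in range(0, len(scan), 37):
            pose = RigidPose(np.eye(3), scan.tips[i])
            p = reconstruct_point(pose, scan.beam_dirs[i], scan.distances[i])
            np.testing.assert_allclose(p, scan.true_hits[i], atol=1e-9)

    def test_frame_equivariance(self, rng):
        R, t = random_rotation(rng), rng.uniform(-5, 5, 3)
        pose = RigidPose(np.eye(3), np.array([1.0, 2.0, 3.0]))
        axis, d = np.array([0.0, 0.6, -0.8]), 9.0
        p = reconstruct_point(pose, axis, d)
        moved = RigidPose(R @ pose.rotation, R @ pose.translation + t)
        p2 = reconstruct_point(moved, axis, d)
        np.testing.assert_allclose(p2, R @ p + t, atol=1e-12)

    def test_invalid_distance_rejected(self):
        pose = RigidPose(np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            reconstruct_point(pose, [0, 0, -1.0], -1.0)


class TestRetinalPointBuffer:
    def test_scan_range_matches_brute_force(self, rng):
        buf = RetinalPointBuffer()
        pts = rng.uniform(-10, 10, (80, 3))
        for i, p in enumerate(pts):
            buf.add(p)
            brute = max(
                np.linalg.norm(pts[a] - pts[b])
                for a in range(i + 1) for b in range(i + 1)
            ) if i else 0.0
            assert buf.scan_range == pytest.approx(brute)

    def test_scan_range_non_decreasing(self, rng):
        buf = RetinalPointBuffer()
        prev = 0.0
        for p in rng.uniform(-5, 5, (60, 3)):
            buf.add(p)
            assert buf.scan_range >= prev
            prev = buf.scan_range


def _stub_ef(semi, valid=True, rms=0.001):
    ell = EllipsoidParams(np.asarray(semi, dtype=float), np.eye(3), np.zeros(3))
    q = QuadricCoefficients(1, 1, 1, 0, 0, 0, 0, 0, 0, -1)
    if not valid:
        return EllipsoidFitResult(None, q, np.inf, False)
    return EllipsoidFitResult(ell, q, rms, True)


@pytest.fixture
def stubbed_model(monkeypatch):
    """Model whose EF results and SF residuals are scripted per tick."""
    script = {"ef": [], "sf_rms": 1.0}

    def fake_ef(points, compute_residual=True):
        return script["ef"].pop(0)

    monkeypatch.setattr(adaptive, "ef_fit", fake_ef)
    monkeypatch.setattr(adaptive, "sphere_rms_residual", lambda pts, s: script["sf_rms"])
    cfg = TransitionConfig(ef_cadence=1, min_ef_points=1)
    model = AdaptiveEyeModel(cfg)
    return model, script


class TestCriteriaSemantics:
    def test_range_threshold_strict(self, stubbed_model, rng):
        model, script = stubbed_model
        # two points 19.9 mm apart: range criterion false
        script["ef"] = [_stub_ef([12, 12, 12])] * 4
        model.update([0, 0, 0]); model.update([19.9, 0, 0])
        assert not model.criteria_status["range"]
        model.update([20.1, 0, 0])  # now spans 20.1 mm
        assert model.criteria_status["range"]

    def test_invalid_ef_blocks_confidence(self, stubbed_model):
        model, script = stubbed_model
        script["ef"] = [_stub_ef([12, 12, 12], valid=False)] * 6
        script["sf_rms"] = 100.0  # even with terrible SF, invalid EF loses
        for i in range(6):
            model.update([float(i), 0.0, 0.0])
        assert not model.criteria_status["confidence"]

    def test_stability_counter_requires_16_consecutive_updates(self, stubbed_model):
        model, script = stubbed_model
        script["ef"] = [_stub_ef([12, 11, 10])] * 40
        for i in range(15):
            model.update([float(i), 0.0, 0.0])
            assert not model.criteria_status["stability"], f"tick {i + 1}"
        model.update([15.0, 0.0, 0.0])  # 16th identical fit
        assert model.criteria_status["stability"]

    def test_axis_change_resets_stability_streak(self, stubbed_model):
        model, script = stubbed_model
        script["ef"] = [_stub_ef([12, 11, 10])] * 10 + [_stub_ef([12.1, 11, 10])] \
            + [_stub_ef([12.1, 11, 10])] * 20
        for i in range(11):
            model.update([float(i), 0.0, 0.0])
        assert model.stability_streak == 1  # reset by the 0.8% jump
        for i in range(15):
            model.update([11.0 + i, 0.0, 0.0])
        assert model.criteria_status["stability"]

    def test_transition_requires_all_three_and_is_monotone(self, stubbed_model):
        model, script = stubbed_model
        good = _stub_ef([12, 11, 10], rms=0.001)
        bad = _stub_ef([12, 11, 10], valid=False)
        script["ef"] = [good] * 30 + [bad] * 5
        script["sf_rms"] = 0.01  # EF residual below SF: confidence ok
        for i in range(30):
            model.update([float(i), 0.0, 0.0])
        assert model.mode == "ellipsoid"
        ti = model.transition_index
        assert ti is not None
        # criteria were simultaneously true at the transition tick
        row = [r for r in model.log if r["n_points"] == ti][0]
        assert row["range_ok"] and row["confidence_ok"] and row["stability_ok"]
        # mode never reverts even when EF later degrades
        for i in range(5):
            model.update([100.0 + i, 0.0, 0.0])
        assert model.mode == "ellipsoid"
        assert model.transition_index == ti


class TestEndToEndAdaptive:
    def test_noiseless_ellipsoid_feed_transitions(self, rng):
        e = EllipsoidParams(np.array([13.0, 12.0, 11.0]), np.eye(3), np.zeros(3))
        u = rng.normal(size=(600, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = e.surface_points(u)
        model = AdaptiveEyeModel(TransitionConfig())
        for p in pts:
            model.update(p)
        assert model.mode == "ellipsoid"
        surface = model.current_surface()
        np.testing.assert_allclose(np.sort(surface.semi_axes), [11, 12, 13], rtol=1e-4)

    def test_finalize_forces_full_buffer_fit(self, rng):
        e = EllipsoidParams(np.array([13.0, 12.0, 11.0]), np.eye(3), np.zeros(3))
        u = rng.normal(size=(103, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        model = AdaptiveEyeModel(TransitionConfig())
        for p in e.surface_points(u):
            model.update(p)
        model.finalize()
        assert model.log[-1]["n_points"] == 103
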