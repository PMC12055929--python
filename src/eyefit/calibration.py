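"""Distance-sensor pose calibration against a planar target.

The 1D distance sensor's pose relative to the robot flange (a 3-vector
offset and a unit beam axis in the flange frame) is estimated from
distance measurements to a static plate taken at many flange poses, using
only the constraint that all reconstructed points must lie on one plane.
The plate pose itself is not assumed known: the objective is the smallest
principal-component variance of the reconstructed point set, which
co-estimates the plane implicitly. Roll about the beam axis is
unobservable from 1D distances and is not parameterized (5 free
parameters: 3 offset + 2 axis direction).

The optimizer is sequential least squares programming (SLSQP) followed by
a Levenberg-Marquardt polish on the out-of-plane residual vector for
tight convergence on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import RigidPose

__all__ = [
    "SensorPose",
    "CalibrationDataset",
    "CalibrationResult",
    "UnobservableError",
    "simulate_calibration_data",
    "calibrate_sensor_pose",
    "pose_sensitivity_analysis",
    "make_sphere_scan_fixture",
]


class UnobservableError(RuntimeError):
    """The pose set cannot constrain the sensor pose (e.g. parallel beams)."""


@dataclass(frozen=True)
class SensorPose:
    """Sensor origin offset (mm) and unit beam axis, both in the flange frame."""

    offset: np.ndarray
    beam_axis: np.ndarray

    def __post_init__(self):
        off = np.asarray(self.offset, dtype=float)
        ax = np.asarray(self.beam_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("beam axis must be a non-zero vector")
        object.__setattr__(self, "offset", off)
        object.__setattr__(self, "beam_axis", ax / n)


@dataclass(frozen=True)
class CalibrationDataset:
    """Flange poses with one plate distance each (plate known only in sim)."""

    flange_poses: tuple
    distances: np.ndarray
    plate_point: np.ndarray | None = None
    plate_normal: np.ndarray | None = None
    n_resampled: int = 0

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        if len(self.flange_poses) != len(self.distances):
            raise ValueError("one distance per flange pose required")
        if len(self.distances) < 6:
            raise ValueError("need at least 6 poses")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    pose: SensorPose
    mean_abs_residual: float
    rms_residual: float
    n_poses: int
    stats: dict = field(default_factory=dict)


def _reconstruct(poses, distances, pose: SensorPose) -> np.ndarray:
    pts = np.empty((len(distances), 3))
    local = pose.offset[None, :] + distances[:, None] * pose.beam_axis[None, :]
    for i, fp in enumerate(poses):
        pts[i] = fp.rotation @ local[i] + fp.translation
    return pts


def _plane_residuals(points: np.ndarray) -> np.ndarray:
    """Signed out-of-plane deviations along the smallest principal component."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[-1]


def _random_rotation_in_cone(rng, half_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = half_angle * rng.uniform()
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def simulate_calibration_data(
    true_pose: SensorPose,
    plate_point=(0.0, 0.0, 0.0),
    plate_normal=(0.0, 0.0, 1.0),
    n_poses: int = 250,
    noise_sigma: float = 0.0,
    seed: int = 0,
    cone_half_angle: float = np.deg2rad(30.0),
    translation_range: float = 20.0,
    standoff: float = 15.0,
) -> CalibrationDataset:
    """Synthetic plate-measurement dataset for calibration fixtures.

    Flange poses are drawn in a 30-degree rotation cone with +/-20 mm
    translations around a nominal standoff above the plate; beams nearly
    parallel to the plate (or not hitting it) are resampled and counted.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    n_hat = np.asarray(plate_normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    p0 = np.asarray(plate_point, dtype=float)
    poses, dists = [], []
    n_resampled = 0
    while len(poses) < n_poses:
        R = _random_rotation_in_cone(rng, cone_half_angle)
        t = p0 + standoff * n_hat + rng.uniform(-translation_range, translation_range, 3)
        origin = R @ true_pose.offset + t
        direction = R @ true_pose.beam_axis
        denom = float(n_hat @ direction)
        if abs(denom) < 0.1:
            n_resampled += 1
            continue
        d = float(n_hat @ (p0 - origin)) / denom
        if not (0.5 < d < 80.0):
            n_resampled += 1
            continue
        poses.append(RigidPose(R, t))
        dists.append(d)
    dists = np.asarray(dists)
    if noise_sigma > 0:
        dists = dists + rng.normal(0.0, noise_sigma, n_poses)
    return CalibrationDataset(tuple(poses), dists, p0, n_hat, n_resampled)


def _axis_basis(axis: np.ndarray):
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return a, u, v


def calibrate_sensor_pose(data: CalibrationDataset, initial_guess: SensorPose) -> CalibrationResult:
    """Estimate the sensor pose from the plane-constrained dataset.

    Parameterization: offset (3) plus two tangent components tilting the
    axis away from the initial guess (roll-free). The SLSQP solution is
    polished with a Levenberg-Marquardt pass on the residual vector.
    """
    poses = data.flange_poses
    dirs_world = np.array([fp.rotation @ initial_guess.beam_axis for fp in poses])
    if np.linalg.matrix_rank(dirs_world - dirs_world.mean(axis=0), tol=1e-6) < 2:
        raise UnobservableError("beam directions span fewer than two axes")
    a0, u, v = _axis_basis(initial_guess.beam_axis)

    def unpack(x):
        axis = a0 + x[3] * u + x[4] * v
        return SensorPose(x[:3], axis)

    def residuals(x):
        return _plane_residuals(_reconstruct(poses, data.distances, unpack(x)))

    def objective(x):
        r = residuals(x)
        return float(r @ r) / len(r)

    x0 = np.r_[initial_guess.offset, 0.0, 0.0]
    res = optimize.minimize(
        objective, x0, method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    lm = optimize.least_squares(residuals, res.x, method="lm", xtol=1e-15, ftol=1e-15)
    pose = unpack(lm.x)
    r = residuals(lm.x)
    return CalibrationResult(
        pose,
        mean_abs_residual=float(np.mean(np.abs(r))),
        rms_residual=float(np.sqrt(np.mean(r**2))),
        n_poses=len(poses),
        stats={"slsqp_iterations": res.nit, "objective": objective(lm.x)},
    )


def make_sphere_scan_fixture(
    true_pose: SensorPose,
    radius: float = 12.0,
    n_samples: int = 400,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Flange poses + distances of a spiral scan over a sphere, for the
    pose sensitivity analysis. The flange orientation is chosen so the
    sensor (at its true pose) reproduces the simulated beam geometry."""
    from .simulate import SimNoise, SpiralConfig, simulate_scan, spiral_trajectory

    cfg = SpiralConfig(theta_max=36.0 * np.pi)
    traj = spiral_trajectory(cfg)
    idx = np.linspace(0, len(traj) - 1, n_samples).astype(int)
    sphere_center = np.zeros(3)
    from .geometry import SphereParams

    surface = SphereParams(sphere_center, radius)
    rcm = np.array([0.0, 0.0, radius])
    scan = simulate_scan(traj[idx], surface, rcm, SimNoise(noise_sigma, seed))
    a0, u, v = _axis_basis(true_pose.beam_axis)
    poses = []
    for tip, d in zip(scan.tips, scan.beam_dirs):
        # rotation mapping the sensor axis onto the simulated beam direction
        b0, bu, bv = _axis_basis(d)
        R = np.column_stack([bu, bv, b0]) @ np.column_stack([u, v, a0]).T
        poses.append(RigidPose(R, tip - R @ true_pose.offset))
    return {
        "flange_poses": tuple(poses),
        "distances": scan.distances.copy(),
        "true_pose": true_pose,
        "true_diameter": 2.0 * radius,
    }


def pose_sensitivity_analysis(fixture: dict, vertical_offsets, rotations_rad):
    """Absolute sphere-diameter error over a grid of sensor-pose errors.

    Each grid cell perturbs the assumed sensor pose (offset shifted
    vertically in the flange frame; beam axis rotated in the image plane),
    reconstructs the retinal points and fits a sphere; reported is
    ``|fitted diameter - true diameter|`` in mm.
    """
    import pandas as pd

    from .fitting import batch_sphere_fit

    true_pose: SensorPose = fixture["true_pose"]
    poses, dists = fixture["flange_poses"], fixture["distances"]
    a0, u, v = _axis_basis(true_pose.beam_axis)
    rows = []
    for dv in np.atleast_1d(vertical_offsets):
        for dr in np.atleast_1d(rotations_rad):
            axis = np.cos(dr) * a0 + np.sin(dr) * u
            pose = SensorPose(true_pose.offset + dv * np.array([0.0, 0.0, 1.0]), axis)
            pts = _reconstruct(poses, dists, pose)
            fit = batch_sphere_fit(pts)
            rows.append(
                {
                    "vertical_offset": float(dv),
                    "rotation": float(dr),
                    "diameter_error": abs(2.0 * fit.sphere.radius - fixture["true_diameter"]),
                }
            )
    return pd.DataFrame(rows)
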