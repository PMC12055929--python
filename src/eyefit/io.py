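"""File I/O helpers: point clouds (CSV/ascii PLY), scans (CSV), meshes (STL),
fit results and calibration datasets (JSON/CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipsoidParams, RigidPose, SphereParams
from .simulate import ScanData

__all__ = [
    "write_point_cloud_csv",
    "read_point_cloud_csv",
    "write_point_cloud_ply",
    "read_point_cloud_ply",
    "write_scan_csv",
    "read_scan_csv",
    "export_mesh_stl",
    "fit_result_to_json",
    "write_calibration_csv",
    "read_calibration_csv",
]


def write_point_cloud_csv(path, points, timestamps=None):
    pts = np.atleast_2d(points)
    data = {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}
    if timestamps is not None:
        data["t"] = np.asarray(timestamps)
    pd.DataFrame(data).to_csv(path, index=False)


def read_point_cloud_csv(path):
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float) if "t" in df.columns else None
    return pts, t


def write_point_cloud_ply(path, points):
    """ASCII PLY point cloud."""
    pts = np.atleast_2d(points)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_point_cloud_ply(path):
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n = 0
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            if line == "end_header":
                break
        pts = np.loadtxt(fh, max_rows=n)
    return np.atleast_2d(pts)[:, :3]


_SCAN_COLUMNS = ["t", "tip_x", "tip_y", "tip_z", "dir_x", "dir_y", "dir_z", "distance"]


def write_scan_csv(path, scan: ScanData):
    pd.DataFrame(
        np.column_stack([scan.t, scan.tips, scan.beam_dirs, scan.distances]),
        columns=_SCAN_COLUMNS,
    ).to_csv(path, index=False)


def read_scan_csv(path) -> ScanData:
    df = pd.read_csv(path)
    tips = df[["tip_x", "tip_y", "tip_z"]].to_numpy(dtype=float)
    dirs = df[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float)
    dist = df["distance"].to_numpy(dtype=float)
    hits = tips + dist[:, None] * dirs
    return ScanData(df["t"].to_numpy(dtype=float), tips, dirs, dist, hits)


def export_mesh_stl(path, mesh, ascii_format: bool = False):
    path = Path(path)
    mesh.export(path, file_type="stl_ascii" if ascii_format else "stl")


def _rotation_to_quaternion(R: np.ndarray) -> list:
    """Unit quaternion (w, x, y, z) of a rotation matrix."""
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        w = 0.25 * s
        x = (R[2, 1] - R[1, 2]) / s
        y = (R[0, 2] - R[2, 0]) / s
        z = (R[1, 0] - R[0, 1]) / s
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2
        q = [0.0, 0.0, 0.0, 0.0]
        q[i + 1] = 0.25 * s
        q[0] = (R[k, j] - R[j, k]) / s
        q[j + 1] = (R[j, i] + R[i, j]) / s
        q[k + 1] = (R[k, i] + R[i, k]) / s
        w, x, y, z = q
    return [float(w), float(x), float(y), float(z)]


def fit_result_to_json(path, model, rms_residual: float | None = None,
                       n_points: int | None = None, valid: bool = True):
    """Serialize a fitted sphere or ellipsoid to JSON."""
    if isinstance(model, SphereParams):
        payload = {
            "model": "sphere",
            "center": model.center.tolist(),
            "radius": float(model.radius),
        }
    elif isinstance(model, EllipsoidParams):
        payload = {
            "model": "ellipsoid",
            "center": model.center.tolist(),
            "semi_axes": model.semi_axes.tolist(),
            "rotation_quaternion_wxyz": _rotation_to_quaternion(model.rotation),
        }
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    payload["valid"] = bool(valid)
    if rms_residual is not None:
        payload["rms_residual"] = float(rms_residual)
    if n_points is not None:
        payload["n_points"] = int(n_points)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def write_calibration_csv(path, dataset):
    rows = []
    for pose, d in zip(dataset.flange_poses, dataset.distances):
        rows.append(np.r_[pose.rotation.ravel(), pose.translation, d])
    cols = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz", "distance"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_calibration_csv(path):
    from .calibration import CalibrationDataset

    df = pd.read_csv(path)
    poses = []
    for _, row in df.iterrows():
        R = row[[f"r{i}{j}" for i in range(3) for j in range(3)]].to_numpy(float).reshape(3, 3)
        poses.append(RigidPose(R, row[["tx", "ty", "tz"]].to_numpy(float)))
    return CalibrationDataset(tuple(poses), df["distance"].to_numpy(float))
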