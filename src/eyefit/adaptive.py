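"""The intraoperative adaptive eye model.

Retinal points reconstructed from sensor pose + axial distance feed an
online sphere fit continuously; an ellipsoid fit is re-attempted on a
fixed cadence of accepted points. The model starts spherical and
transitions (one-way) to the ellipsoid once three criteria hold
simultaneously at an ellipsoid-fit tick:

1. *Scan range* — the greatest pairwise distance among reconstructed
   points exceeds 20 mm, so the data spans enough of the globe.
2. *Model confidence* — the ellipsoid's geometric RMS residual on the
   accumulated points is below the sphere's.
3. *Temporal stability* — the maximum relative change of the three
   semi-axes between consecutive ellipsoid updates stays below 0.03 %
   for more than 15 consecutive updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    EllipsoidFitResult,
    KalmanState,
    ef_fit,
    sf_update,
    sphere_from_state,
    sphere_kalman_init,
    sphere_rms_residual,
)
from .geometry import RigidPose

__all__ = [
    "TransitionConfig",
    "RetinalPointBuffer",
    "AdaptiveEyeModel",
    "reconstruct_point",
    "evaluate_transition_criteria",
    "update_model",
]


@dataclass(frozen=True)
class TransitionConfig:
    """Thresholds of the three sphere-to-ellipsoid transition criteria."""

    range_threshold: float = 20.0          # mm of scan range
    variation_threshold: float = 0.0003    # 0.03 % relative semi-axis change
    consecutive_iterations: int = 15       # EF updates the stability must span
    ef_cadence: int = 5                    # accepted points between EF re-fits
    min_ef_points: int = 10                # points before the first EF attempt

    def __post_init__(self):
        if min(self.range_threshold, self.variation_threshold,
               self.consecutive_iterations, self.ef_cadence, self.min_ef_points) <= 0:
            raise ValueError("all transition parameters must be positive")


class RetinalPointBuffer:
    """Ordered, timestamped retinal points with an exact running scan range.

    The scan range (greatest pairwise distance) is maintained incrementally:
    each insertion checks the new point against all stored points, which is
    exact and O(n) per insertion.
    """

    def __init__(self):
        self._pts = np.empty((256, 3))
        self._t = np.empty(256)
        self._n = 0
        self.scan_range = 0.0

    def __len__(self):
        return self._n

    @property
    def points(self) -> np.ndarray:
        return self._pts[: self._n]

    @property
    def timestamps(self) -> np.ndarray:
        return self._t[: self._n]

    def add(self, point, t: float = np.nan):
        p = np.asarray(point, dtype=float).reshape(3)
        if self._n == len(self._pts):
            self._pts = np.concatenate([self._pts, np.empty_like(self._pts)])
            self._t = np.concatenate([self._t, np.empty_like(self._t)])
        if self._n:
            d = np.linalg.norm(self._pts[: self._n] - p, axis=1).max()
            self.scan_range = max(self.scan_range, float(d))
        self._pts[self._n] = p
        self._t[self._n] = t
        self._n += 1


def reconstruct_point(sensor_pose: RigidPose, beam_axis, distance: float) -> np.ndarray:
    """World retinal point: sensor position + distance along the beam."""
    if not (np.isfinite(distance) and distance > 0):
        raise ValueError("distance must be positive and finite")
    axis = np.asarray(beam_axis, dtype=float)
    world_dir = sensor_pose.rotation @ axis
    return sensor_pose.translation + distance * world_dir


class AdaptiveEyeModel:
    """Stateful adaptive model: sphere mode -> ellipsoid mode.

    Feed points with :meth:`update`; query :attr:`mode`,
    :attr:`transition_index` and :meth:`current_surface`. The transition is
    monotone: once ellipsoidal, the mode never reverts.
    """

    def __init__(self, config: TransitionConfig | None = None,
                 kalman: KalmanState | None = None):
        self.config = config if config is not None else TransitionConfig()
        self.buffer = RetinalPointBuffer()
        self.kalman = kalman if kalman is not None else sphere_kalman_init()
        self.mode = "sphere"
        self.last_ef: EllipsoidFitResult | None = None
        self.last_sf_rms = np.nan
        self.transition_index: int | None = None
        self.criteria_status = {"range": False, "confidence": False, "stability": False}
        self._prev_axes: np.ndarray | None = None
        self.stability_streak = 0
        self.last_axis_variation = np.nan
        self.n_ticks = 0
        self.ticked = False  # whether the most recent update ran an EF tick
        self.log: list[dict] = []

    # -- updates ---------------------------------------------------------

    def update(self, point, t: float = np.nan) -> "AdaptiveEyeModel":
        """Append a reconstructed retinal point and advance the model."""
        p = np.asarray(point, dtype=float).reshape(3)
        self.ticked = False
        if not np.all(np.isfinite(p)):
            return self
        self.buffer.add(p, t)
        self.kalman = sf_update(self.kalman, p)
        n = len(self.buffer)
        if n >= self.config.min_ef_points and n % self.config.ef_cadence == 0:
            self._ef_tick()
        return self

    def _ef_tick(self):
        cfg = self.config
        pts = self.buffer.points
        ef = ef_fit(pts)
        sf_rms = np.nan
        if self.kalman.mature:
            try:
                sf_rms = sphere_rms_residual(pts, sphere_from_state(self.kalman))
            except ValueError:  # degenerate data: sphere not identifiable yet
                pass
        variation = np.nan
        if ef.valid:
            axes = ef.ellipsoid.semi_axes
            if self._prev_axes is not None:
                variation = float(np.max(np.abs(axes - self._prev_axes) / self._prev_axes))
                self.stability_streak = (
                    self.stability_streak + 1 if variation < cfg.variation_threshold else 1
                )
            else:
                self.stability_streak = 1
            self._prev_axes = axes
        else:
            self._prev_axes = None
            self.stability_streak = 0
        self.last_ef = ef
        self.last_sf_rms = sf_rms
        self.last_axis_variation = variation
        self.n_ticks += 1
        self.ticked = True
        self.criteria_status = {
            "range": self.buffer.scan_range > cfg.range_threshold,
            "confidence": bool(ef.valid and np.isfinite(sf_rms) and ef.rms_residual < sf_rms),
            "stability": self.stability_streak > cfg.consecutive_iterations,
        }
        if self.mode == "sphere" and all(self.criteria_status.values()):
            self.mode = "ellipsoid"
            self.transition_index = len(self.buffer)
        self.log.append(
            {
                "n_points": len(self.buffer),
                "scan_range": self.buffer.scan_range,
                "sf_rms": sf_rms,
                "ef_rms": ef.rms_residual if ef.valid else np.nan,
                "ef_valid": ef.valid,
                "axis_variation": variation,
                "range_ok": self.criteria_status["range"],
                "confidence_ok": self.criteria_status["confidence"],
                "stability_ok": self.criteria_status["stability"],
                "mode": self.mode,
            }
        )

    def finalize(self) -> "AdaptiveEyeModel":
        """Force a final EF tick on the complete buffer (cadence-independent)."""
        if len(self.buffer) >= self.config.min_ef_points and (
            not self.log or self.log[-1]["n_points"] != len(self.buffer)
        ):
            self._ef_tick()
        return self

    # -- queries ---------------------------------------------------------

    def sphere(self):
        return sphere_from_state(self.kalman)

    def current_surface(self):
        """The active model surface (ellipsoid after transition)."""
        if self.mode == "ellipsoid" and self.last_ef is not None and self.last_ef.valid:
            return self.last_ef.ellipsoid
        return self.sphere()

    def criteria_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def evaluate_transition_criteria(model: AdaptiveEyeModel) -> dict:
    """Per-criterion booleans as of the most recent ellipsoid-fit tick."""
    return dict(model.criteria_status)


def update_model(model: AdaptiveEyeModel, new_point, t: float = np.nan) -> AdaptiveEyeModel:
    """Functional alias for :meth:`AdaptiveEyeModel.update`."""
    return model.update(new_point, t)
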