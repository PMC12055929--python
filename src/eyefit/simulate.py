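"""Scan simulation: spiral trajectories, beam-surface intersection, A-scans.

The instrument tip follows an Archimedean spiral
``f(theta) = (b*theta/2pi * cos(theta), b*theta/2pi * sin(theta), 0)``
in the coronal plane through the eye center, with theta reparameterized by
arc length so consecutive trajectory points are equispaced. The instrument
shaft is a straight line through a remote center of motion (RCM) at the
trocar, so the measurement beam of each sample points from the RCM through
the tip. The simulated distance is the range from the tip to the first
beam-surface intersection, perturbed by Gaussian sensor noise on the
distance only (poses are exact, matching the repeatability of the robot
relative to the OCT noise scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EllipsoidParams, SphereParams
from .shapes import EyeShapeSurface

__all__ = [
    "SpiralConfig",
    "SimNoise",
    "ScanSample",
    "ScanData",
    "spiral_trajectory",
    "simulate_scan",
    "generate_ascan",
    "OCT_RATE_HZ",
    "OCT_IMAGING_DEPTH_MM",
    "OCT_N_SAMPLES",
    "OCT_PITCH_MM",
]

OCT_RATE_HZ = 2000.0
OCT_IMAGING_DEPTH_MM = 60.0
OCT_N_SAMPLES = 1024
OCT_PITCH_MM = OCT_IMAGING_DEPTH_MM / OCT_N_SAMPLES
#: interface peak width, within the engine's 30-40 um axial resolution
OCT_AXIAL_RESOLUTION_MM = 0.035


@dataclass(frozen=True)
class SpiralConfig:
    """Archimedean spiral scan parameters (b = loop spacing in mm)."""

    b: float = 0.5
    theta_max: float = 36.0 * np.pi  # 18 revolutions
    arc_spacing: float = 0.1
    plane_z: float = 0.0  # coronal plane through the eye center

    def __post_init__(self):
        if self.b <= 0 or self.arc_spacing <= 0 or self.theta_max <= 0:
            raise ValueError("b, arc_spacing and theta_max must be positive")


@dataclass(frozen=True)
class SimNoise:
    """Gaussian distance-noise model (sigma in mm, default 20 um)."""

    sigma: float = 0.020
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class ScanSample:
    """One timestamped measurement: tip pose, beam direction, distance."""

    t: float
    tip: np.ndarray
    beam_dir: np.ndarray
    distance: float
    true_hit: np.ndarray


class ScanData:
    """A scan stream as flat arrays (valid samples only).

    ``n_invalid`` counts trajectory points whose beam missed the surface.
    """

    def __init__(self, t, tips, beam_dirs, distances, true_hits, n_invalid=0):
        self.t = np.asarray(t, dtype=float)
        self.tips = np.asarray(tips, dtype=float)
        self.beam_dirs = np.asarray(beam_dirs, dtype=float)
        self.distances = np.asarray(distances, dtype=float)
        self.true_hits = np.asarray(true_hits, dtype=float)
        self.n_invalid = int(n_invalid)

    def __len__(self):
        return len(self.t)

    def __getitem__(self, i: int) -> ScanSample:
        return ScanSample(
            float(self.t[i]), self.tips[i], self.beam_dirs[i],
            float(self.distances[i]), self.true_hits[i],
        )

    def reconstructed_points(self) -> np.ndarray:
        """Retinal points: tip + measured distance along the beam."""
        return self.tips + self.distances[:, None] * self.beam_dirs


def _spiral_arc_length(theta: np.ndarray, b: float) -> np.ndarray:
    # closed form of integral of (b/2pi) sqrt(1 + theta^2)
    return (b / (4.0 * np.pi)) * (theta * np.sqrt(1.0 + theta**2) + np.arcsinh(theta))


def spiral_point(theta, b: float, plane_z: float = 0.0) -> np.ndarray:
    """The Archimedean spiral map f(theta) itself (radius b*theta/2pi)."""
    theta = np.asarray(theta, dtype=float)
    radius = b * theta / (2.0 * np.pi)
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta),
         np.full_like(theta, plane_z)], axis=-1,
    )


def spiral_trajectory(cfg: SpiralConfig) -> np.ndarray:
    """Arc-length equispaced points of the Archimedean spiral, starting at
    the eye center."""
    theta_dense = np.linspace(0.0, cfg.theta_max, 200_001)
    s_dense = _spiral_arc_length(theta_dense, cfg.b)
    targets = np.arange(0.0, s_dense[-1] + 1e-12, cfg.arc_spacing)
    theta = np.interp(targets, s_dense, theta_dense)
    radius = cfg.b * theta / (2.0 * np.pi)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full_like(theta, cfg.plane_z)]
    )


def _ray_ellipsoid_first_hit(tips, dirs, ell: EllipsoidParams):
    """Smallest positive ray parameter of the ellipsoid intersection."""
    inv = ell.rotation / ell.semi_axes  # columns scaled: maps via x @ inv
    p = (tips - ell.center) @ inv
    v = dirs @ inv
    a = (v * v).sum(axis=1)
    bq = 2.0 * (p * v).sum(axis=1)
    cq = (p * p).sum(axis=1) - 1.0
    disc = bq**2 - 4.0 * a * cq
    valid = disc >= 0
    sq = np.sqrt(np.where(valid, disc, 0.0))
    t1 = (-bq - sq) / (2.0 * a)
    t2 = (-bq + sq) / (2.0 * a)
    t = np.where(t1 > 1e-12, t1, t2)
    valid &= t > 1e-12
    return t, valid


def _ray_generic_first_hit(tips, dirs, surface: EyeShapeSurface, t_max=60.0, coarse=0.25):
    """First sign change of the implicit along each ray, refined by bisection."""
    ts = np.arange(0.0, t_max + coarse, coarse)
    n = len(tips)
    first = np.full(n, -1, dtype=int)
    prev = surface.implicit(tips)
    inside0 = prev <= 0
    for k in range(1, len(ts)):
        pts = tips + ts[k] * dirs
        vals = surface.implicit(pts)
        crossing = (first < 0) & (prev <= 0) & (vals > 0)
        first[crossing] = k
        prev = vals
        if np.all(first >= 0):
            break
    valid = (first >= 0) & inside0
    lo = np.where(valid, ts[np.maximum(first, 1) - 1], 0.0)
    hi = np.where(valid, ts[np.maximum(first, 1)], coarse)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        vals = surface.implicit(tips + mid[:, None] * dirs)
        go_hi = vals > 0
        hi = np.where(go_hi, mid, hi)
        lo = np.where(go_hi, lo, mid)
    return 0.5 * (lo + hi), valid


def _first_intersections(tips, dirs, surface):
    if isinstance(surface, SphereParams):
        surface = EllipsoidParams(
            np.full(3, surface.radius), np.eye(3), surface.center
        )
    if isinstance(surface, EllipsoidParams):
        return _ray_ellipsoid_first_hit(tips, dirs, surface)
    if isinstance(surface, EyeShapeSurface):
        if surface.ellipsoid is not None:
            return _ray_ellipsoid_first_hit(tips, dirs, surface.ellipsoid)
        return _ray_generic_first_hit(tips, dirs, surface)
    raise TypeError(f"unsupported surface type {type(surface).__name__}")


def simulate_scan(traj, surface, rcm, noise: SimNoise | None = None,
                  rate_hz: float = OCT_RATE_HZ) -> ScanData:
    """Simulate one iiOCT measurement per trajectory point.

    The beam of each sample points from the RCM through the tip
    (tip-forward); the measured distance is the tip-to-surface range along
    the beam plus Gaussian noise. Ground-truth hits are stored noise-free.
    Samples whose beam misses the surface are excluded and counted.
    """
    tips = np.atleast_2d(np.asarray(traj, dtype=float))
    rcm = np.asarray(rcm, dtype=float)
    noise = noise if noise is not None else SimNoise()
    vec = tips - rcm
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("trajectory point coincides with the RCM")
    dirs = vec / norms[:, None]
    ranges, valid = _first_intersections(tips, dirs, surface)
    rng = np.random.Generator(np.random.Philox(key=noise.seed))
    eps = rng.normal(0.0, noise.sigma, len(tips)) if noise.sigma > 0 else np.zeros(len(tips))
    t = np.arange(len(tips)) / rate_hz
    hits = tips + ranges[:, None] * dirs
    return ScanData(
        t[valid], tips[valid], dirs[valid],
        (ranges + eps)[valid], hits[valid], n_invalid=int((~valid).sum()),
    )


def generate_ascan(true_distance: float, pitch: float = OCT_PITCH_MM,
                   n_samples: int = OCT_N_SAMPLES, peak_amplitude: float = 10.0,
                   background: float = 1.0,
                   axial_resolution: float = OCT_AXIAL_RESOLUTION_MM,
                   seed: int | None = 0):
    """Synthesize one A-scan intensity profile.

    A Gaussian interface peak of width ~ the axial resolution sits at
    ``true_distance / pitch`` on top of Rayleigh speckle (``background``
    is the speckle scale; 0 disables it). The speckle is generated in a
    frame attached to the interface, so two A-scans sharing a seed but
    differing in distance are shifted copies of each other — the
    "similar intensity-value distribution" that template matching relies
    on. Returns an :class:`eyefit.ascan.AScan`.
    """
    from .ascan import AScan

    if not (0.0 < true_distance < pitch * n_samples):
        raise ValueError("distance outside the imaging range")
    x = np.arange(n_samples, dtype=float)
    center = true_distance / pitch
    sigma = axial_resolution / pitch / 2.355  # FWHM -> std
    profile = peak_amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if background > 0 and seed is not None:
        rng = np.random.Generator(np.random.Philox(key=seed))
        # tissue-attached speckle: one long pattern, windowed so that it
        # shifts together with the interface position
        pattern = rng.rayleigh(background, 3 * n_samples)
        start = n_samples - int(round(center))
        profile = profile + pattern[start : start + n_samples]
    return AScan(intensities=profile, pitch=pitch, t=0.0)
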