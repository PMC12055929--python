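"""Geometric primitives: spheres, ellipsoids and general quadrics.

All coordinates are millimetres in a right-handed, eye-centered frame:
+z points anterior along the visual (length) axis, +x along the eye's
width and +y along its height.

The module provides the conversions between the algebraic quadric form

    a x^2 + b y^2 + c z^2 + 2 f y z + 2 g x z + 2 h x y
        + 2 p x + 2 q y + 2 r z + d = 0

and the geometric ellipsoid form ``{R D eta + omega : eta in S^2}``
(semi-axis matrix ``D``, rotation ``R``, center ``omega``), the
ellipsoid-specific acceptance test on the coefficients, exact
point-to-surface distances, and the cropped spherical surface sampling
used by the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateQuadricError",
    "NotAnEllipsoidError",
    "SphereParams",
    "EllipsoidParams",
    "QuadricCoefficients",
    "RigidPose",
    "evaluate_ellipsoid_constraint",
    "quadric_to_ellipsoid",
    "ellipsoid_to_quadric",
    "point_to_surface_distance",
    "surface_distances",
    "sample_surface_cropped",
]

_ORTHO_TOL = 1e-9


class DegenerateQuadricError(ValueError):
    """The quadric's parameter matrix is (numerically) singular."""


class NotAnEllipsoidError(ValueError):
    """The quadric does not describe an ellipsoid."""


def as_point(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("point coordinates must be finite")
    return arr


@dataclass(frozen=True)
class SphereParams:
    """Sphere with center (x0, y0, z0) in mm and radius r > 0."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("sphere radius must be positive and finite")


@dataclass(frozen=True)
class EllipsoidParams:
    """Geometric ellipsoid: semi-axes (diagonal of D), rotation R, center.

    The surface is ``{R @ diag(semi_axes) @ eta + center : |eta| = 1}``.
    """

    semi_axes: np.ndarray
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        semi = np.asarray(self.semi_axes, dtype=float)
        rot = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "semi_axes", semi)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "center", as_point(self.center))
        if semi.shape != (3,) or not np.all(semi > 0):
            raise ValueError("semi-axes must be three positive lengths")
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.max(np.abs(rot @ rot.T - np.eye(3))) > 1e-8:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def to_principal(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the ellipsoid's principal frame."""
        return (np.atleast_2d(points) - self.center) @ self.rotation

    def surface_points(self, eta: np.ndarray) -> np.ndarray:
        """Map unit-sphere directions ``eta`` (N,3) onto the surface."""
        return (np.atleast_2d(eta) * self.semi_axes) @ self.rotation.T + self.center


@dataclass(frozen=True)
class RigidPose:
    """Rigid transform (rotation + translation), e.g. a robot flange pose."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", as_point(self.translation))
        if rot.shape != (3, 3) or np.max(np.abs(rot @ rot.T - np.eye(3))) > _ORTHO_TOL:
            raise ValueError("rotation must be orthonormal within 1e-9")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class QuadricCoefficients:
    """The ten algebraic coefficients (a, b, c, f, g, h, p, q, r, d)."""

    a: float
    b: float
    c: float
    f: float
    g: float
    h: float
    p: float
    q: float
    r: float
    d: float

    @property
    def matrix(self) -> np.ndarray:
        """The symmetric 3x3 parameter matrix A."""
        return np.array(
            [
                [self.a, self.h, self.g],
                [self.h, self.b, self.f],
                [self.g, self.f, self.c],
            ]
        )

    @property
    def linear(self) -> np.ndarray:
        return np.array([self.p, self.q, self.r])

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.c, self.f, self.g, self.h, self.p, self.q, self.r, self.d]
        )

    @classmethod
    def from_vector(cls, v) -> "QuadricCoefficients":
        v = np.asarray(v, dtype=float)
        if v.shape != (10,):
            raise ValueError("expected 10 coefficients")
        if np.all(v == 0):
            raise ValueError("all-zero quadric")
        return cls(*v)

    @classmethod
    def from_matrices(cls, A, linear, d) -> "QuadricCoefficients":
        A = np.asarray(A, dtype=float)
        p, q, r = np.asarray(linear, dtype=float)
        return cls(A[0, 0], A[1, 1], A[2, 2], A[1, 2], A[0, 2], A[0, 1], p, q, r, float(d))

    def normalized(self) -> "QuadricCoefficients":
        """Scale to unit coefficient norm with trace(A) > 0 (fixed storage form)."""
        v = self.as_vector()
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("all-zero quadric")
        v = v / n
        tr = v[0] + v[1] + v[2]
        if tr < 0 or (tr == 0 and v[np.nonzero(v)[0][0]] < 0):
            v = -v
        return QuadricCoefficients.from_vector(v)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate x^T A x + 2 (p,q,r).x + d at the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.matrix
        vals = np.einsum("ni,ij,nj->n", pts, A, pts) + 2.0 * pts @ self.linear + self.d
        return vals if np.asarray(points).ndim == 2 else vals[0]


def evaluate_ellipsoid_constraint(q: QuadricCoefficients) -> float:
    """Ellipsoid acceptance value 4(ab+bc+ac-f^2-g^2-h^2) - (a+b+c)^2.

    Strictly positive iff the quadratic part is accepted as ellipsoidal.
    The value scales with the square of any common coefficient scaling,
    so its sign is scale-free.
    """
    return float(
        4.0 * (q.a * q.b + q.b * q.c + q.a * q.c - q.f**2 - q.g**2 - q.h**2)
        - (q.a + q.b + q.c) ** 2
    )


def quadric_to_ellipsoid(q: QuadricCoefficients) -> EllipsoidParams:
    """Recover semi-axes, rotation and center from quadric coefficients.

    The center is ``-A^{-1} (p,q,r)``; after normalizing the centered
    equation to unit constant, the semi-axes are ``1/sqrt(|lambda_i|)`` of
    the eigenvalues of the normalized parameter matrix and the eigenvectors
    form the columns of the rotation. Axes are ordered by descending
    semi-axis length and eigenvector signs fixed so det(R) = +1.
    """
    if evaluate_ellipsoid_constraint(q) <= 0:
        raise NotAnEllipsoidError("quadratic part is not ellipsoidal")
    A = q.matrix
    if np.linalg.cond(A) > 1e12:
        raise DegenerateQuadricError("singular parameter matrix")
    sol = np.linalg.solve(A, q.linear)
    center = -sol
    # centered equation: x'^T A x' = k with k = b^T A^{-1} b - d
    k = float(q.linear @ sol - q.d)
    if k == 0:
        raise NotAnEllipsoidError("degenerate (point) quadric")
    lam, vec = np.linalg.eigh(A / k)
    if np.any(lam <= 0):
        raise NotAnEllipsoidError("surface is not a real ellipsoid")
    semi = 1.0 / np.sqrt(np.abs(lam))
    order = np.argsort(-semi)
    semi = semi[order]
    rot = vec[:, order].copy()
    if np.linalg.det(rot) < 0:
        rot[:, -1] *= -1.0
    return EllipsoidParams(semi, rot, center)


def ellipsoid_to_quadric(e: EllipsoidParams) -> QuadricCoefficients:
    """Inverse of :func:`quadric_to_ellipsoid` (up to normalization)."""
    M = e.rotation @ np.diag(1.0 / e.semi_axes**2) @ e.rotation.T
    linear = -M @ e.center
    d = float(e.center @ M @ e.center - 1.0)
    return QuadricCoefficients.from_matrices(M, linear, d).normalized()


def _ellipsoid_distances(points: np.ndarray, e: EllipsoidParams, iters: int = 60) -> np.ndarray:
    """Exact unsigned distances from points to an ellipsoid surface.

    Solves, per point, the orthogonal-projection (Lagrange) condition
    ``F(t) = sum_i (d_i y_i / (t + d_i^2))^2 - 1 = 0`` in the principal
    frame. F is convex and strictly decreasing on the admissible interval
    and ``t0 = max_i (d_i y_i - d_i^2)`` satisfies ``F(t0) >= 0``, so
    Newton iteration from t0 converges monotonically (no safeguarding
    needed) and quadratically.
    """
    pts = np.atleast_2d(points)
    d = e.semi_axes
    d2 = d**2
    y = np.abs(e.to_principal(pts))
    # nudge exact-zero components off the symmetry planes: keeps the
    # Lagrange root unique, at an error far below any tolerance here
    y = np.maximum(y, 1e-13 * d.max())
    dy = y * d
    dy2 = dy**2
    t = (dy - d2).max(axis=1)
    for _ in range(iters):
        denom = t[:, None] + d2[None, :]
        F = (dy2 / denom**2).sum(axis=1) - 1.0
        if np.all(np.abs(F) < 1e-14):
            break
        dF = -2.0 * (dy2 / denom**3).sum(axis=1)
        t = t - F / dF
    x = d2 * y / (t[:, None] + d2[None, :])
    return np.linalg.norm(y - x, axis=1)


def surface_distances(points: np.ndarray, surface) -> np.ndarray:
    """Vectorized unsigned point-to-surface distances (sphere or ellipsoid)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(surface, SphereParams):
        return np.abs(np.linalg.norm(pts - surface.center, axis=1) - surface.radius)
    if isinstance(surface, EllipsoidParams):
        return _ellipsoid_distances(pts, surface)
    raise TypeError(f"unsupported surface type {type(surface).__name__}")


def point_to_surface_distance(pt, surface) -> float:
    """Exact unsigned Euclidean distance from a point to a sphere/ellipsoid."""
    return float(surface_distances(as_point(pt)[None, :], surface)[0])


def _sphere_grid(n_u: int, n_v: int) -> np.ndarray:
    """Unit directions on a (theta, phi) grid; theta measured from +z."""
    theta = np.linspace(0.0, np.pi, n_u)
    phi = np.linspace(0.0, 2.0 * np.pi, n_v, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    st = np.sin(tt)
    return np.column_stack(
        [(st * np.cos(pp)).ravel(), (st * np.sin(pp)).ravel(), np.cos(tt).ravel()]
    )


def sample_surface_cropped(
    surface, n_u: int, n_v: int, crop_depth: float = 0.0
) -> np.ndarray:
    """Sample a sphere/ellipsoid on an n_u x n_v spherical grid, then drop
    every point within ``crop_depth`` of the surface's anterior (+z) extreme.

    Uniform (theta, phi) angle grids are used; theta runs pole-to-pole so a
    ``crop_depth`` of zero returns exactly ``n_u * n_v`` points.
    """
    if n_u < 2 or n_v < 2:
        raise ValueError("n_u and n_v must both be >= 2")
    if crop_depth < 0:
        raise ValueError("crop_depth must be non-negative")
    eta = _sphere_grid(n_u, n_v)
    if isinstance(surface, SphereParams):
        pts = eta * surface.radius + surface.center
    elif isinstance(surface, EllipsoidParams):
        pts = surface.surface_points(eta)
    else:
        raise TypeError(f"unsupported surface type {type(surface).__name__}")
    z_max = pts[:, 2].max()
    keep = pts[:, 2] <= z_max - crop_depth + 1e-12
    if not np.any(keep):
        raise ValueError("crop removed every sampled point")
    return pts[keep]
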