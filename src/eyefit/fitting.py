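"""Sphere and ellipsoid fitting.

Sphere fitting (SF) is online: the sphere equation is rearranged into a
linear observation on the parameter vector
``beta = (2 x0, 2 y0, 2 z0, r^2 - x0^2 - y0^2 - z0^2)`` with observation
row ``(x, y, z, 1)`` and measurement ``x^2 + y^2 + z^2``, and a linear
Kalman filter updates ``beta`` per point. With a diffuse prior and zero
process noise the filter reproduces the batch linear least-squares
solution, so SF behaves as recursive least squares.

Ellipsoid fitting (EF) is batch: the general quadric is fit by least
squares subject to the ellipsoid-specific inequality
``4(ab+bc+ac-f^2-g^2-h^2) - (a+b+c)^2 > 0``, solved directly through a
generalized eigen-decomposition of the design scatter against the
constraint's quadratic form (no iterative nonlinear optimization), after
centering/scaling the data for conditioning. Geometric parameters are
recovered from the quadric; residuals are geometric RMS distances so SF
and EF confidences are on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    EllipsoidParams,
    NotAnEllipsoidError,
    DegenerateQuadricError,
    QuadricCoefficients,
    SphereParams,
    evaluate_ellipsoid_constraint,
    quadric_to_ellipsoid,
    surface_distances,
)

__all__ = [
    "KalmanState",
    "SphereFitResult",
    "EllipsoidFitResult",
    "ImmatureStateError",
    "DEFAULT_MEASUREMENT_VARIANCE",
    "sphere_kalman_init",
    "sf_update",
    "sphere_from_state",
    "batch_sphere_fit",
    "sphere_rms_residual",
    "ef_fit",
]

#: nominal eye radius (mm) used for the radius prior and noise scaling
NOMINAL_RADIUS_MM = 12.0
#: measurement variance of the linearized sphere observation: the
#: observation error is ~ 2*r*sigma for distance noise sigma (20 um default)
DEFAULT_MEASUREMENT_VARIANCE = (2.0 * NOMINAL_RADIUS_MM * 0.020) ** 2


class ImmatureStateError(RuntimeError):
    """Too few distinct points for the sphere parameters to be identifiable."""


@dataclass(frozen=True)
class KalmanState:
    """Linearized sphere parameter state with covariance."""

    beta: np.ndarray
    covariance: np.ndarray
    n_points: int = 0

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        if self.beta.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("beta must be a 4-vector and covariance 4x4")

    @property
    def mature(self) -> bool:
        return self.n_points >= 4


@dataclass(frozen=True)
class SphereFitResult:
    sphere: SphereParams
    rms_residual: float


@dataclass(frozen=True)
class EllipsoidFitResult:
    ellipsoid: EllipsoidParams | None
    quadric: QuadricCoefficients
    rms_residual: float
    valid: bool


def sphere_kalman_init(radius_prior: float = NOMINAL_RADIUS_MM,
                       prior_variance: float = 1e4) -> KalmanState:
    """Diffuse-prior filter state centered on a nominal eye at the origin."""
    beta0 = np.array([0.0, 0.0, 0.0, radius_prior**2])
    return KalmanState(beta0, prior_variance * np.eye(4), 0)


def sf_update(state: KalmanState, point,
              measurement_variance: float = DEFAULT_MEASUREMENT_VARIANCE) -> KalmanState:
    """One Kalman measurement update with a new retinal point.

    Zero process noise; the Joseph-form covariance update keeps the
    covariance symmetric positive-definite. Non-finite points are
    rejected (state returned unchanged).
    """
    p = np.asarray(point, dtype=float).reshape(-1)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        return state
    H = np.array([p[0], p[1], p[2], 1.0])
    z = float(p @ p)
    P = state.covariance
    S = float(H @ P @ H) + measurement_variance
    K = (P @ H) / S
    beta = state.beta + K * (z - float(H @ state.beta))
    IKH = np.eye(4) - np.outer(K, H)
    P_new = IKH @ P @ IKH.T + measurement_variance * np.outer(K, K)
    P_new = 0.5 * (P_new + P_new.T)
    return KalmanState(beta, P_new, state.n_points + 1)


def sphere_from_state(state: KalmanState) -> SphereParams:
    """Geometric sphere from the linearized state vector."""
    if not state.mature:
        raise ImmatureStateError("need at least 4 points to identify a sphere")
    center = state.beta[:3] / 2.0
    r2 = float(state.beta[3] + center @ center)
    if r2 <= 0:
        raise ValueError("non-physical state: negative squared radius")
    return SphereParams(center, float(np.sqrt(r2)))


def batch_sphere_fit(points: np.ndarray) -> SphereFitResult:
    """Batch linear least-squares sphere fit (the offline analogue of SF)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    H = np.column_stack([pts, np.ones(len(pts))])
    z = (pts**2).sum(axis=1)
    beta, *_ = np.linalg.lstsq(H, z, rcond=None)
    center = beta[:3] / 2.0
    r2 = float(beta[3] + center @ center)
    if r2 <= 0:
        raise ValueError("degenerate point set: negative squared radius")
    sphere = SphereParams(center, float(np.sqrt(r2)))
    return SphereFitResult(sphere, sphere_rms_residual(pts, sphere))


def sphere_rms_residual(points: np.ndarray, sphere: SphereParams) -> float:
    """Geometric RMS distance of points to the sphere surface."""
    return float(np.sqrt(np.mean(surface_distances(points, sphere) ** 2)))


# quadratic form of the ellipsoid constraint on (a, b, c, f, g, h):
# 4(ab+bc+ac-f^2-g^2-h^2) - (a+b+c)^2 = v^T C1 v
_C1 = np.array(
    [
        [-1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        [1.0, -1.0, 1.0, 0.0, 0.0, 0.0],
        [1.0, 1.0, -1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, -4.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, -4.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, -4.0],
    ]
)


def _design_matrix(pts: np.ndarray) -> np.ndarray:
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    one = np.ones_like(x)
    return np.column_stack(
        [x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y, 2 * x, 2 * y, 2 * z, one]
    )


def _denormalize_quadric(v: np.ndarray, mu: np.ndarray, s: float) -> QuadricCoefficients:
    """Map quadric coefficients fit in x' = (x - mu)/s back to world frame."""
    q = QuadricCoefficients.from_vector(v)
    A = q.matrix / s**2
    linear = q.linear / s - (q.matrix @ mu) / s**2
    d = float(mu @ q.matrix @ mu) / s**2 - 2.0 * float(q.linear @ mu) / s + q.d
    return QuadricCoefficients.from_matrices(A, linear, d).normalized()


def ef_fit(points: np.ndarray, compute_residual: bool = True) -> EllipsoidFitResult:
    """Direct constrained least-squares ellipsoid fit.

    Returns a result with ``valid=False`` (quadric still reported) when no
    generalized eigenvector satisfies the ellipsoid constraint or when the
    geometric recovery fails; a hyperboloid is never returned silently as
    an ellipsoid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 9:
        raise ValueError("need at least 9 points for an ellipsoid fit")
    mu = pts.mean(axis=0)
    s = float(np.mean(np.linalg.norm(pts - mu, axis=1))) or 1.0
    D = _design_matrix((pts - mu) / s)
    S = D.T @ D
    S11, S12, S22 = S[:6, :6], S[:6, 6:], S[6:, 6:]
    try:
        T = -np.linalg.solve(S22, S12.T)
    except np.linalg.LinAlgError:
        T = -np.linalg.pinv(S22) @ S12.T
    M = np.linalg.solve(_C1, S11 + S12 @ T)
    eigvals, eigvecs = np.linalg.eig(M)
    best_u, best_res = None, np.inf
    fallback_u, fallback_res = None, np.inf
    for i in range(6):
        if abs(eigvals[i].imag) > 1e-8 * (1.0 + abs(eigvals[i].real)):
            continue
        u = np.real(eigvecs[:, i])
        cval = float(u @ _C1 @ u)
        v = np.concatenate([u, T @ u])
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        res = float(v @ S @ v) / nv**2
        if cval > 0:
            if res < best_res:
                best_u, best_res = v, res
        elif res < fallback_res:
            fallback_u, fallback_res = v, res
    if best_u is None:
        quadric = _denormalize_quadric(
            fallback_u if fallback_u is not None else np.r_[np.ones(3), np.zeros(6), -1.0],
            mu, s,
        )
        return EllipsoidFitResult(None, quadric, np.inf, False)
    quadric = _denormalize_quadric(best_u, mu, s)
    if evaluate_ellipsoid_constraint(quadric) <= 0:
        return EllipsoidFitResult(None, quadric, np.inf, False)
    try:
        ellipsoid = quadric_to_ellipsoid(quadric)
    except (NotAnEllipsoidError, DegenerateQuadricError):
        return EllipsoidFitResult(None, quadric, np.inf, False)
    rms = np.nan
    if compute_residual:
        rms = float(np.sqrt(np.mean(surface_distances(pts, ellipsoid) ** 2)))
    return EllipsoidFitResult(ellipsoid, quadric, rms, True)
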